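"""Shared fixtures: one simulated study reused across the suite."""

import numpy as np
import pandas as pd
import pytest

from methcrosstalk import (SimConfig, assign_chromatin_states, simulate_genome,
                           simulate_mbd_library)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def annotation(sim_config):
    return simulate_genome(sim_config)


@pytest.fixture(scope="session")
def truth_and_peaks(annotation, sim_config):
    return assign_chromatin_states(annotation, sim_config)


@pytest.fixture(scope="session")
def truth(truth_and_peaks):
    return truth_and_peaks[0]


@pytest.fixture(scope="session")
def mark_peaks(truth_and_peaks):
    return truth_and_peaks[1]


@pytest.fixture(scope="session")
def control_library(annotation, truth, sim_config):
    return simulate_mbd_library(annotation, truth, "control", sim_config)


@pytest.fixture(scope="session")
def kd_library(annotation, truth, sim_config):
    return simulate_mbd_library(annotation, truth, "siKD", sim_config)


@pytest.fixture()
def toy_genes():
    """Small hand-built gene table on one 100-kb chromosome."""
    return pd.DataFrame({
        "name": ["geneA", "geneB", "geneC"],
        "chrom": ["chr1", "chr1", "chr1"],
        "strand": ["+", "-", "+"],
        "tx_start": [10_000, 40_000, 70_000],
        "tx_end": [20_000, 50_000, 80_000],
    })


@pytest.fixture()
def toy_chrom_lengths():
    return {"chr1": 100_000}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
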