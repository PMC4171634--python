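"""End-to-end orchestration: simulate -> call islands -> differential ->
annotate/rollup -> profiles -> matrix/cluster -> enrichment.

Stages persist plain files into an output directory and a JSON manifest
records parameters, seeds and per-stage row counts; rerunning with the same
configuration and seed reproduces every output byte for byte.  With
``resume=True`` a stage whose outputs already exist on disk is loaded
instead of recomputed, so deleting an intermediate regenerates only the
downstream stages.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import core, diffmeth, enrichment, profiles
from .islands import CallerParams, call_differential, call_islands, merge_intervals
from .synthetic import (KnockdownEffect, SimConfig, assign_chromatin_states,
                        simulate_genome, simulate_mbd_library)

logger = logging.getLogger(__name__)

EXIT_CONFIG_ERROR = 2
EXIT_STAGE_FAILURE = 3


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    caller: CallerParams = field(default_factory=CallerParams)
    fold_threshold: float = 2.0
    run_profiles: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        try:
            sim_raw = dict(raw.get("sim", {}))
            if "kd_effects" in sim_raw:
                sim_raw["kd_effects"] = [
                    KnockdownEffect(**e) if isinstance(e, dict)
                    else KnockdownEffect(*e)
                    for e in sim_raw["kd_effects"]
                ]
            seed = int(raw.get("seed", 0))
            sim_raw.setdefault("seed", seed)
            cfg = cls(
                sim=SimConfig(**sim_raw),
                caller=CallerParams(**raw.get("caller", {})),
                fold_threshold=float(raw.get("fold_threshold", 2.0)),
                run_profiles=bool(raw.get("run_profiles", True)),
                seed=seed,
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"invalid pipeline configuration: {exc}") from exc
        return cfg


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: PipelineConfig, outdir, resume: bool = False) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written to
    ``outdir``/manifest.json)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "caller_params": asdict(config.caller),
        "sim_params": _jsonable(asdict(config.sim)),
        "fold_threshold": config.fold_threshold,
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("libraries", _stage_libraries),
        ("islands", _stage_islands),
        ("differential", _stage_differential),
        ("rollup", _stage_rollup),
        ("profiles", _stage_profiles),
        ("matrix", _stage_matrix),
        ("enrichment", _stage_enrichment),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            info = fn(config, out, state, resume)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            raise StageFailure(name, exc) from exc
        info["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][name] = info
        logger.info("stage %-12s %s", name, info)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(config, out, state, resume):
    genes_path = out / "genes.refflat"
    cgi_path = out / "cgi.bed"
    fasta_path = out / "promoters.fa"
    states_path = out / "promoter_states.tsv"
    peak_paths = {m: out / f"{m}_peaks.bed" for m in ("k4me3", "k27me3", "h2aub")}
    meth_path = out / "truth_meth.tsv"
    feat_path = out / "truth_features.tsv"

    annotation = simulate_genome(config.sim)
    truth, peaks = assign_chromatin_states(annotation, config.sim)
    state["annotation"] = annotation
    state["truth"] = truth
    state["peaks"] = peaks

    core.write_refflat(annotation.genes, genes_path)
    core.write_bed(annotation.cgis, cgi_path)
    core.write_fasta(annotation.promoter_seqs, fasta_path)
    truth.states.to_csv(states_path, sep="\t", index=False)
    for mark, path in peak_paths.items():
        core.write_bed(peaks[mark], path)
    truth.meth.to_csv(meth_path, sep="\t")
    truth.features.to_csv(feat_path, sep="\t", index=False)
    return {"n_genes": len(annotation.genes), "n_cgis": len(annotation.cgis)}


def _stage_libraries(config, out, state, resume):
    libs = {}
    counts = {}
    for condition in config.sim.conditions:
        path = out / f"tags_{condition}.bed"
        if resume and path.exists():
            libs[condition] = core.TagLibrary.from_bed(path, condition)
        else:
            libs[condition] = simulate_mbd_library(
                state["annotation"], state["truth"], condition, config.sim)
            libs[condition].to_bed(path)
        counts[condition] = libs[condition].size
    state["libraries"] = libs
    return {"library_sizes": counts}


def _stage_islands(config, out, state, resume):
    chrom_lengths = state["annotation"].chrom_lengths
    islands = {}
    counts = {}
    for condition, lib in state["libraries"].items():
        path = out / f"islands_{condition}.tsv"
        if resume and path.exists():
            islands[condition] = pd.read_csv(path, sep="\t")
        else:
            islands[condition] = call_islands(lib, chrom_lengths, config.caller)
            islands[condition].to_csv(path, sep="\t", index=False)
        counts[condition] = len(islands[condition])
    state["islands"] = islands
    return {"n_islands": counts}


def _stage_differential(config, out, state, resume):
    chrom_lengths = state["annotation"].chrom_lengths
    control = config.sim.conditions[0]
    diff = {}
    counts = {}
    for condition in config.sim.conditions[1:]:
        path = out / f"diff_{condition}.tsv"
        if resume and path.exists():
            diff[condition] = pd.read_csv(path, sep="\t")
        else:
            union = merge_intervals([state["islands"][condition],
                                     state["islands"][control]])
            diff[condition] = call_differential(
                union, state["libraries"][condition],
                state["libraries"][control], chrom_lengths, config.caller)
            diff[condition].to_csv(path, sep="\t", index=False)
        counts[condition] = int(diff[condition]["significant"].sum())
    state["differential"] = diff
    return {"n_significant": counts}


def _stage_rollup(config, out, state, resume):
    # per-feature (FPKM-based) differential avoids island-span dilution of
    # promoter fold changes; the island-level regions stay on disk alongside
    control = config.sim.conditions[0]
    calls = []
    for condition in state["differential"]:
        path = out / f"calls_{condition}.tsv"
        if resume and path.exists():
            c = pd.read_csv(path, sep="\t")
        else:
            feat = diffmeth.feature_differential(
                state["libraries"][condition], state["libraries"][control],
                state["annotation"], config.caller)
            feat.to_csv(out / f"feature_diff_{condition}.tsv", sep="\t",
                        index=False)
            c = diffmeth.gene_level_rollup(feat, state["annotation"],
                                           condition, config.fold_threshold)
            c.to_csv(path, sep="\t", index=False)
        calls.append(c)
    all_calls = (pd.concat(calls, ignore_index=True) if calls
                 else pd.DataFrame(columns=["gene", "feature_class",
                                            "condition", "log2_change",
                                            "status"]))
    state["calls"] = all_calls
    summary = diffmeth.rollup_counts(all_calls)
    summary.to_csv(out / "call_counts.tsv", sep="\t", index=False)
    return {"n_calls": len(all_calls)}


def _stage_profiles(config, out, state, resume):
    if not config.run_profiles:
        return {"skipped": True}
    annotation = state["annotation"]
    spec = profiles.ProfileSpec(mode="metagene")
    info = {}
    for condition, lib in state["libraries"].items():
        path = out / f"metagene_{condition}.tsv"
        if not (resume and path.exists()):
            prof = profiles.metagene_profile(lib, annotation.genes,
                                             annotation.chrom_lengths, spec,
                                             config.caller.fragment_size)
            prof.to_csv(path, sep="\t", index=False)
        info[condition] = str(path.name)
    # promoter point profiles stratified by CpG class
    classes = ann.classify_all_promoters(annotation)
    merged = annotation.genes.merge(classes, left_on="name", right_on="gene")
    tss = np.where(merged["strand"] == "+", merged["tx_start"], merged["tx_end"])
    anchors = pd.DataFrame({"chrom": merged["chrom"], "pos": tss,
                            "strand": merged["strand"],
                            "cpg_class": merged["cpg_class"]})
    pspec = profiles.ProfileSpec(mode="point", upstream_bp=5000,
                                 downstream_bp=5000)
    for condition, lib in state["libraries"].items():
        for cls in ("HCP", "ICP", "LCP"):
            sub = anchors[anchors["cpg_class"] == cls]
            if sub.empty:
                continue
            path = out / f"tss_{cls}_{condition}.tsv"
            if not (resume and path.exists()):
                prof = profiles.point_profile(lib, sub,
                                              annotation.chrom_lengths, pspec,
                                              config.caller.fragment_size)
                prof.to_csv(path, sep="\t", index=False)
    return info


def _stage_matrix(config, out, state, resume):
    calls = state["calls"]
    matrix = diffmeth.build_call_matrix(calls, "promoter")
    matrix.to_csv(out / "call_matrix.tsv", sep="\t")
    state["matrix"] = matrix
    if len(matrix) >= 2 and matrix.shape[1] >= 1:
        clust = diffmeth.hierarchical_cluster(matrix)
        clust["ordered"].to_csv(out / "call_matrix_clustered.tsv", sep="\t")
        (out / "call_matrix_rows.nwk").write_text(clust["row_newick"] + "\n")
        return {"n_rows": len(matrix), "clustered": True}
    return {"n_rows": len(matrix), "clustered": False}


def _stage_enrichment(config, out, state, resume):
    truth = state["truth"]
    universe = list(state["annotation"].genes["name"])
    calls = state["calls"]
    results = {}
    for condition in config.sim.conditions[1:]:
        for status in ("hyper", "hypo"):
            genes = set(calls[(calls["condition"] == condition)
                              & (calls["feature_class"] == "promoter")
                              & (calls["status"] == status)]["gene"])
            if not genes:
                continue
            res = enrichment.state_enrichment(genes, truth.states, universe)
            path = out / f"state_enrichment_{condition}_{status}.tsv"
            res.to_csv(path, sep="\t", index=False)
            results[f"{condition}:{status}"] = len(genes)
    state["enrichment_call_sizes"] = results
    return {"call_set_sizes": results}
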