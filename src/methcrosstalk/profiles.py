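"""Tag-density profiles and FPKM tables.

Coverage is summarized as FPKM-style normalized density: midpoint-counted
tags per kilobase of bin per million mapped tags.  Metagene profiles use
fixed-width flank bins and relative-length body bins (0% = TSS, 100% = TTS);
point profiles use fixed-width bins centered on an anchor.  A maximum of two
tags per genomic position is retained before profiling (stricter duplicate
handling than the caller's redundancy rule; the two arms of the pipeline use
different conventions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TagLibrary
from .islands import deduplicate_tags, tag_midpoints

logger = logging.getLogger(__name__)

PROFILE_MAX_PER_POSITION = 2
LOG2_PSEUDO_FRACTION = 0.1


@dataclass
class ProfileSpec:
    mode: str = "metagene"  # "metagene" | "point"
    upstream_bp: int = 10_000
    downstream_bp: int = 10_000
    n_flank_bins: int = 100
    n_body_bins: int = 100
    n_point_bins: int = 100
    log2_output: bool = False

    def __post_init__(self) -> None:
        if min(self.n_flank_bins, self.n_body_bins, self.n_point_bins) <= 0:
            raise ValueError("bin counts must be positive")
        if min(self.upstream_bp, self.downstream_bp) <= 0:
            raise ValueError("bp spans must be positive")


def fpkm(count: float, length: int, library_size: int) -> float:
    """Fragments per kilobase of feature per million mapped fragments."""
    if length <= 0:
        raise ValueError("feature length must be positive")
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return count / ((length / 1000.0) * (library_size / 1e6))


def profile_midpoints(library: TagLibrary, fragment_size: int,
                      chrom_lengths: dict[str, int],
                      max_per_position: int = PROFILE_MAX_PER_POSITION
                      ) -> tuple[dict[str, np.ndarray], int]:
    """Midpoints for profiling after the max-per-position duplicate rule.

    Returns (midpoints per chromosome, retained library size).
    """
    lib = deduplicate_tags(library, max_per_position)
    return tag_midpoints(lib, fragment_size, chrom_lengths), lib.size


def _bin_counts(mids: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Counts per bin for monotonically increasing edges (len = nbins + 1)."""
    idx = np.searchsorted(mids, edges)
    return np.diff(idx)


def metagene_profile(library: TagLibrary, genes: pd.DataFrame,
                     chrom_lengths: dict[str, int],
                     spec: ProfileSpec | None = None,
                     fragment_size: int = 300) -> pd.DataFrame:
    """Average normalized tag density from -upstream of the TSS, across the
    length-normalized gene body, to +downstream of the TTS.

    Output columns: bin (0-based), segment (upstream/body/downstream),
    rel_pos (bp for flanks, percent for body), density (mean FPKM-normalized
    coverage over genes), n_genes.
    """
    spec = spec or ProfileSpec(mode="metagene")
    mids, lib_size = profile_midpoints(library, fragment_size, chrom_lengths)
    n_up, n_body, n_down = spec.n_flank_bins, spec.n_body_bins, spec.n_flank_bins
    total_bins = n_up + n_body + n_down
    acc = np.zeros(total_bins)
    used = 0
    up_w = spec.upstream_bp / n_up
    down_w = spec.downstream_bp / n_down
    for _, g in genes.iterrows():
        length = int(g["tx_end"] - g["tx_start"])
        if length < spec.n_body_bins:
            logger.info("metagene: skipping %s (%d bp < %d body bins)",
                        g["name"], length, spec.n_body_bins)
            continue
        m = mids.get(g["chrom"], np.zeros(0, dtype=np.int64))
        if g["strand"] == "+":
            up_edges = g["tx_start"] - spec.upstream_bp + np.arange(n_up + 1) * up_w
            body_edges = np.linspace(g["tx_start"], g["tx_end"], n_body + 1)
            down_edges = g["tx_end"] + np.arange(n_down + 1) * down_w
            edges = np.concatenate([up_edges, body_edges[1:-1], down_edges])
        else:
            # mirrored: upstream of a minus-strand gene is to the right
            up_edges = g["tx_end"] + spec.upstream_bp - np.arange(n_up + 1) * up_w
            body_edges = np.linspace(g["tx_end"], g["tx_start"], n_body + 1)
            down_edges = g["tx_start"] - np.arange(n_down + 1) * down_w
            edges = np.concatenate([up_edges, body_edges[1:-1], down_edges])[::-1]
        counts = _bin_counts(m, np.round(edges).astype(np.int64))
        if g["strand"] == "-":
            counts = counts[::-1]
        widths = np.diff(np.round(edges))
        if g["strand"] == "-":
            widths = widths[::-1]
        widths = np.maximum(widths, 1.0)
        acc += counts * 1e6 / lib_size / (widths / 1000.0)
        used += 1
    if used == 0:
        raise ValueError("no gene long enough for the requested body bins")
    density = acc / used
    segment = (["upstream"] * n_up + ["body"] * n_body + ["downstream"] * n_down)
    rel = np.concatenate([
        -spec.upstream_bp + (np.arange(n_up) + 0.5) * up_w,
        (np.arange(n_body) + 0.5) * 100.0 / n_body,
        (np.arange(n_down) + 0.5) * down_w,
    ])
    out = pd.DataFrame({"bin": np.arange(total_bins), "segment": segment,
                        "rel_pos": rel, "density": density, "n_genes": used})
    if spec.log2_output:
        out["density_log2"] = _log2_with_floor(out["density"].to_numpy())
    return out


def _log2_with_floor(x: np.ndarray) -> np.ndarray:
    pseudo = LOG2_PSEUDO_FRACTION * float(np.mean(x))
    if pseudo <= 0:
        pseudo = 1e-9
    return np.log2(x + pseudo)


def point_profile(library: TagLibrary, anchors: pd.DataFrame,
                  chrom_lengths: dict[str, int],
                  spec: ProfileSpec | None = None,
                  fragment_size: int = 300) -> pd.DataFrame:
    """Average normalized density in fixed-width bins centered on anchors.

    ``anchors`` has columns chrom, pos and optionally strand (minus-strand
    anchors are orientation-flipped before averaging).
    """
    spec = spec or ProfileSpec(mode="point", upstream_bp=5000, downstream_bp=5000)
    mids, lib_size = profile_midpoints(library, fragment_size, chrom_lengths)
    n_bins = spec.n_point_bins
    span = spec.upstream_bp + spec.downstream_bp
    width = span / n_bins
    acc = np.zeros(n_bins)
    used = 0
    has_strand = "strand" in anchors.columns
    for _, a in anchors.iterrows():
        m = mids.get(a["chrom"], np.zeros(0, dtype=np.int64))
        edges = a["pos"] - spec.upstream_bp + np.arange(n_bins + 1) * width
        counts = _bin_counts(m, np.round(edges).astype(np.int64))
        if has_strand and a["strand"] == "-":
            counts = counts[::-1]
        acc += counts * 1e6 / lib_size / (width / 1000.0)
        used += 1
    if used == 0:
        raise ValueError("no anchors supplied")
    density = acc / used
    rel = -spec.upstream_bp + (np.arange(n_bins) + 0.5) * width
    out = pd.DataFrame({"bin": np.arange(n_bins), "rel_pos": rel,
                        "density": density, "n_anchors": used})
    if spec.log2_output:
        out["density_log2"] = _log2_with_floor(density)
    return out


def feature_fpkm_table(library: TagLibrary, features: pd.DataFrame,
                       chrom_lengths: dict[str, int],
                       fragment_size: int = 300,
                       max_per_position: int = PROFILE_MAX_PER_POSITION
                       ) -> pd.DataFrame:
    """Midpoint-counted tags and FPKM per feature (chrom/start/end rows,
    extra columns passed through); deterministic row order."""
    feats = features.reset_index(drop=True)
    if ((feats["end"] - feats["start"]) <= 0).any():
        raise ValueError("degenerate feature intervals (end <= start)")
    mids, lib_size = profile_midpoints(library, fragment_size, chrom_lengths,
                                       max_per_position)
    counts = np.zeros(len(feats), dtype=np.int64)
    for chrom, sub in feats.groupby("chrom"):
        m = mids.get(chrom, np.zeros(0, dtype=np.int64))
        lo = np.searchsorted(m, sub["start"].to_numpy())
        hi = np.searchsorted(m, sub["end"].to_numpy())
        counts[sub.index.to_numpy()] = hi - lo
    out = feats.copy()
    out["count"] = counts
    lengths = (out["end"] - out["start"]).to_numpy()
    out["fpkm"] = counts / ((lengths / 1000.0) * (lib_size / 1e6))
    return out
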