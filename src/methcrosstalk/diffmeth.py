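"""Hyper/hypomethylation calling, the cross-condition change matrix, and the
array / qPCR validation computations.

A gene feature is called hypermethylated in a knockdown when its
log2 methylation change is at least +1 (2-fold or greater), hypomethylated
at -1 or below; the boundary is inclusive.  Per-condition calls roll up to
genes per feature class (promoter, body, 3' end, CGI, shore); a gene may be
simultaneously hyper- and hypomethylated in its body through distinct
regions, and both calls are kept.  Array validation uses the delta-beta
criterion (|delta beta| > 0.2 with p < 0.05, Welch's t across replicate
beta values) and the -1700 bp promoter rule for probe-to-gene assignment;
MeDIP-qPCR enrichment relative to input is 2^-(sample Ct - input Ct).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .annotation import GeneFeatureIndex

FOLD_THRESHOLD = 2.0
INFINIUM_PROMOTER_UP = 1700

FEATURE_CLASSES = ("promoter", "body", "three_prime_end", "cgi", "shore")


def feature_log2_change(fpkm_kd, fpkm_ctrl, pseudocount: float = 0.1):
    """log2((kd + c) / (ctrl + c)); 0 vs 0 gives 0 for any c > 0."""
    kd = np.asarray(fpkm_kd, dtype=float)
    ctrl = np.asarray(fpkm_ctrl, dtype=float)
    out = np.log2((kd + pseudocount) / (ctrl + pseudocount))
    return out if out.ndim else float(out)


def call_feature_status(log2_change, fold_threshold: float = FOLD_THRESHOLD):
    """'hyper' at >= +log2(threshold), 'hypo' at <= -log2(threshold)
    (boundaries inclusive), else 'unchanged'."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    thr = np.log2(fold_threshold)
    x = np.asarray(log2_change, dtype=float)
    out = np.where(x >= thr, "hyper", np.where(x <= -thr, "hypo", "unchanged"))
    return out if out.ndim else str(out)


def _interval_overlaps(regions: pd.DataFrame, intervals: pd.DataFrame
                       ) -> list[tuple[int, int]]:
    """(region index, interval index) pairs with >= 1 bp overlap."""
    pairs = []
    for chrom, sub in regions.groupby("chrom"):
        ivs = intervals[intervals["chrom"] == chrom]
        if ivs.empty:
            continue
        s = ivs["start"].to_numpy()
        e = ivs["end"].to_numpy()
        for ridx, r in sub.iterrows():
            hits = np.flatnonzero((np.minimum(e, r["end"]) -
                                   np.maximum(s, r["start"])) > 0)
            pairs.extend((ridx, ivs.index[h]) for h in hits)
    return pairs


def gene_feature_table(annotation, shore_flank: int = 2000) -> pd.DataFrame:
    """Per-gene feature intervals (promoter, body, 3' end, CGI, shores) as a
    table of (chrom, start, end, gene, feature_class) for direct testing."""
    from .annotation import (promoter_interval, shore_intervals,
                             three_prime_interval)

    rows = []
    for _, g in annotation.genes.iterrows():
        clen = annotation.chrom_lengths[g["chrom"]]
        ps, pe = promoter_interval(g, chrom_length=clen)
        ts, te = three_prime_interval(g, chrom_length=clen)
        rows.append((g["chrom"], ps, pe, g["name"], "promoter"))
        rows.append((g["chrom"], int(g["tx_start"]), int(g["tx_end"]),
                     g["name"], "body"))
        if te > ts:
            rows.append((g["chrom"], ts, te, g["name"], "three_prime_end"))
    idx = GeneFeatureIndex(annotation.genes, annotation.chrom_lengths)
    cgis = annotation.cgis.reset_index(drop=True)
    for _, c in cgis.iterrows():
        _, gene = idx.classify(c["chrom"], int(c["start"]), int(c["end"]))
        host = gene if gene is not None else str(c["name"])
        rows.append((c["chrom"], int(c["start"]), int(c["end"]), host, "cgi"))
        clen = annotation.chrom_lengths[c["chrom"]]
        for s, e in shore_intervals((c["chrom"], int(c["start"]),
                                     int(c["end"])), cgis, flank=shore_flank,
                                    chrom_length=clen):
            if e > s:
                rows.append((c["chrom"], s, e, host, "shore"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene",
                                       "feature_class"])


def feature_differential(lib_kd, lib_ctrl, annotation, params=None,
                         shore_flank: int = 2000) -> pd.DataFrame:
    """FPKM-based differential table over defined gene features.

    Each promoter / body / 3'-end / CGI / shore interval is counted directly
    in both libraries and tested with the same normalized Poisson test and
    BH control as island regions.  This avoids the fold-change dilution that
    occurs when a broad island spans a feature plus unchanged flanking
    sequence.
    """
    from .islands import call_differential

    features = gene_feature_table(annotation, shore_flank)
    return call_differential(features, lib_kd, lib_ctrl,
                             annotation.chrom_lengths, params)


def gene_level_rollup(diff_regions: pd.DataFrame, annotation, condition: str,
                      fold_threshold: float = FOLD_THRESHOLD,
                      require_significant: bool = True,
                      shore_flank: int = 2000) -> pd.DataFrame:
    """Roll differential regions up to per-gene feature-class calls.

    A gene is called hyper (hypo) for a class when at least one passing
    region of that class overlapping the gene reaches the fold threshold.
    CGI and shore calls are recorded in addition to the gene feature class
    of the region.  Returns rows (gene, feature_class, condition,
    log2_change, status); per (gene, class, status) the largest-magnitude
    change is kept.

    ``diff_regions`` may also be a feature table from
    :func:`feature_differential` (recognized by its gene/feature_class
    columns), in which case rows map to calls directly without interval
    classification.
    """
    from .annotation import shore_intervals

    regions = diff_regions.reset_index(drop=True)
    if require_significant and "significant" in regions.columns:
        regions = regions[regions["significant"]].reset_index(drop=True)
    status = call_feature_status(regions["log2_fold_change"].to_numpy(),
                                 fold_threshold)
    regions = regions.assign(status=status)
    regions = regions[regions["status"] != "unchanged"].reset_index(drop=True)

    if {"gene", "feature_class"} <= set(regions.columns):
        calls = regions[["gene", "feature_class", "log2_fold_change",
                         "status"]].rename(
            columns={"log2_fold_change": "log2_change"})
        calls.insert(2, "condition", condition)
        if calls.empty:
            return calls
        calls["abs_change"] = calls["log2_change"].abs()
        return (calls.sort_values(["gene", "feature_class", "status",
                                   "abs_change"],
                                  ascending=[True, True, True, False])
                .drop_duplicates(["gene", "feature_class", "status"])
                .drop(columns="abs_change")
                .reset_index(drop=True))

    idx = GeneFeatureIndex(annotation.genes, annotation.chrom_lengths)
    rows = []
    for _, r in regions.iterrows():
        cls, gene = idx.classify(r["chrom"], int(r["start"]), int(r["end"]))
        if gene is not None:
            rows.append((gene, cls, condition, float(r["log2_fold_change"]),
                         r["status"]))

    # CGI and shore overlap calls, attributed to the CGI's nearest gene class
    cgis = annotation.cgis.reset_index(drop=True)
    for ridx, cidx in _interval_overlaps(regions, cgis):
        r = regions.loc[ridx]
        cgi = cgis.loc[cidx]
        _, gene = idx.classify(cgi["chrom"], int(cgi["start"]), int(cgi["end"]))
        rows.append((gene if gene is not None else str(cgi["name"]), "cgi",
                     condition, float(r["log2_fold_change"]), r["status"]))
    shore_rows = []
    for cidx, cgi in cgis.iterrows():
        for s, e in shore_intervals((cgi["chrom"], int(cgi["start"]), int(cgi["end"])),
                                    cgis, flank=shore_flank,
                                    chrom_length=annotation.chrom_lengths[cgi["chrom"]]):
            shore_rows.append((cgi["chrom"], s, e, cidx))
    shores = pd.DataFrame(shore_rows, columns=["chrom", "start", "end", "cgi_idx"])
    for ridx, sidx in _interval_overlaps(regions, shores):
        r = regions.loc[ridx]
        cgi = cgis.loc[shores.loc[sidx, "cgi_idx"]]
        _, gene = idx.classify(cgi["chrom"], int(cgi["start"]), int(cgi["end"]))
        rows.append((gene if gene is not None else str(cgi["name"]), "shore",
                     condition, float(r["log2_fold_change"]), r["status"]))

    calls = pd.DataFrame(rows, columns=["gene", "feature_class", "condition",
                                        "log2_change", "status"])
    if calls.empty:
        return calls
    calls["abs_change"] = calls["log2_change"].abs()
    calls = (calls.sort_values(["gene", "feature_class", "status", "abs_change"],
                               ascending=[True, True, True, False])
             .drop_duplicates(["gene", "feature_class", "status"])
             .drop(columns="abs_change")
             .reset_index(drop=True))
    return calls


def rollup_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Pie-chart style table: genes per (feature_class, status)."""
    if calls.empty:
        return pd.DataFrame(columns=["feature_class", "status", "n_genes"])
    return (calls.groupby(["feature_class", "status"])["gene"].nunique()
            .rename("n_genes").reset_index())


def build_call_matrix(calls: pd.DataFrame, feature_class: str = "promoter",
                      fill: float = 0.0) -> pd.DataFrame:
    """Genes x conditions matrix of log2 changes for one feature class.

    Rows are genes differentially methylated in at least one condition;
    unchanged/missing cells take ``fill`` (0 = no change) so clustering sees
    a complete matrix.  Pass ``fill=np.nan`` for the NA-masking mode.
    """
    conditions = sorted(calls["condition"].unique()) if not calls.empty else []
    sub = calls[(calls["feature_class"] == feature_class)
                & (calls["status"] != "unchanged")] if not calls.empty else calls
    if sub is None or len(sub) == 0:
        return pd.DataFrame(columns=conditions)
    # a gene hyper and hypo in the same condition keeps the larger magnitude
    sub = sub.assign(abs_change=sub["log2_change"].abs())
    sub = (sub.sort_values("abs_change", ascending=False)
           .drop_duplicates(["gene", "condition"]))
    mat = sub.pivot(index="gene", columns="condition", values="log2_change")
    mat = mat.reindex(columns=conditions).fillna(fill) if not np.isnan(fill) \
        else mat.reindex(columns=conditions)
    return mat.sort_index()


def hierarchical_cluster(matrix: pd.DataFrame) -> dict:
    """Agglomerative clustering (Euclidean distance, average linkage) of the
    call matrix rows and columns.

    Returns ordered matrix, leaf orders, linkage arrays and newick strings.
    A constant matrix yields a single cluster with a warning.
    """
    if matrix.empty:
        raise ValueError("cannot cluster an empty matrix")
    values = matrix.to_numpy(dtype=float)
    if np.allclose(values, values.flat[0]):
        warnings.warn("constant matrix: single cluster", stacklevel=2)
    row_link = hierarchy.linkage(values, method="average", metric="euclidean") \
        if len(matrix) > 1 else None
    col_link = hierarchy.linkage(values.T, method="average", metric="euclidean") \
        if matrix.shape[1] > 1 else None
    row_order = hierarchy.leaves_list(row_link) if row_link is not None else [0]
    col_order = hierarchy.leaves_list(col_link) if col_link is not None else [0]
    ordered = matrix.iloc[row_order, col_order]
    return {
        "ordered": ordered,
        "row_order": list(matrix.index[row_order]),
        "col_order": list(matrix.columns[col_order]),
        "row_linkage": row_link,
        "col_linkage": col_link,
        "row_newick": _linkage_to_newick(row_link, list(matrix.index)),
        "col_newick": _linkage_to_newick(col_link, list(matrix.columns)),
    }


def _linkage_to_newick(link, labels: list) -> str:
    if link is None:
        return f"({labels[0]});" if labels else "();"
    tree = hierarchy.to_tree(link)

    def rec(node):
        if node.is_leaf():
            return str(labels[node.id])
        left, right = rec(node.get_left()), rec(node.get_right())
        return f"({left}:{node.dist:.6g},{right}:{node.dist:.6g})"

    return rec(tree) + ";"


def infinium_diff(beta_kd: pd.DataFrame, beta_ctrl: pd.DataFrame,
                  delta_threshold: float = 0.2, alpha: float = 0.05
                  ) -> pd.DataFrame:
    """Per-probe delta-beta calls between knockdown and control replicates.

    ``beta_kd`` / ``beta_ctrl`` are probes x replicates with a common probe
    index.  delta_beta = mean(kd) - mean(ctrl); p from Welch's t across
    replicates (the per-probe test of the original array software is not
    specified; Welch's t is this package's choice, recorded in the output as
    ``test``).  With a single replicate per arm the call degrades to
    delta-beta-only (test = 'delta_only', p = NaN).
    """
    if not beta_kd.index.equals(beta_ctrl.index):
        raise ValueError("probe sets of the two arms do not match")
    kd = beta_kd.to_numpy(dtype=float)
    ctrl = beta_ctrl.to_numpy(dtype=float)
    delta = kd.mean(axis=1) - ctrl.mean(axis=1)
    if kd.shape[1] >= 2 and ctrl.shape[1] >= 2:
        test = "welch_t"
        with np.errstate(divide="ignore", invalid="ignore"):
            p = stats.ttest_ind(kd, ctrl, axis=1, equal_var=False).pvalue
        zero_var = (kd.std(axis=1) == 0) & (ctrl.std(axis=1) == 0)
        p = np.where(zero_var, np.where(delta != 0, 0.0, 1.0), p)
        called = (np.abs(delta) > delta_threshold) & (p < alpha)
    else:
        test = "delta_only"
        p = np.full(len(delta), np.nan)
        called = np.abs(delta) > delta_threshold
    status = np.where(called & (delta > 0), "hyper",
                      np.where(called & (delta < 0), "hypo", "unchanged"))
    return pd.DataFrame({"probe": beta_kd.index, "delta_beta": delta,
                         "p_value": p, "status": status, "test": test})


def infinium_promoter_rollup(calls: pd.DataFrame, probe_map: pd.DataFrame,
                             genes: pd.DataFrame,
                             up: int = INFINIUM_PROMOTER_UP) -> pd.DataFrame:
    """Per-gene promoter status from probe calls.

    The array-arm promoter is the ``up`` bp immediately upstream of the TSS
    (strand-aware, [TSS - 1700, TSS) on the plus strand); a gene is hyper
    (hypo) when >= 1 probe in that window is so called, and a gene with both
    gets both rows.
    """
    merged = calls.merge(probe_map, on="probe", how="left")
    rows = []
    for _, g in genes.iterrows():
        if g["strand"] == "+":
            lo, hi = g["tx_start"] - up, g["tx_start"]
        else:
            lo, hi = g["tx_end"], g["tx_end"] + up
        inside = merged[(merged["chrom"] == g["chrom"])
                        & (merged["pos"] >= lo) & (merged["pos"] < hi)]
        for st in ("hyper", "hypo"):
            if (inside["status"] == st).any():
                rows.append((g["name"], st,
                             int((inside["status"] == st).sum())))
    return pd.DataFrame(rows, columns=["gene", "status", "n_probes"])


def medip_enrichment(sample_mean_ct, input_mean_ct):
    """MeDIP-qPCR enrichment relative to input: 2^-(sample Ct - input Ct)."""
    s = np.asarray(sample_mean_ct, dtype=float)
    i = np.asarray(input_mean_ct, dtype=float)
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(i))):
        raise ValueError("Ct values must be finite")
    out = np.exp2(-(s - i))
    return out if out.ndim else float(out)
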