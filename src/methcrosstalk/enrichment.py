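"""Chromatin-state stratification and gene-set enrichment statistics.

Promoters are stratified by their H3K4me3 / H3K27me3 / H2AK119ub peak
overlap into six categories; bivalency means K4me3 and K27me3 together,
regardless of H2AK119ub.  Over/under-representation of categories or of
external gene lists among differentially methylated genes is tested with a
two-tailed Fisher exact test (probability-mass convention: the p-value sums
all tables with the observed margins whose probability does not exceed the
observed table's) after the conservative EASE adjustment of the overlap
cell.  The exact test is computed here by direct hypergeometric enumeration
over the table support, which is feasible at any universe size used in
practice and is cross-checked against an independent implementation in the
test suite.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STATE_CATEGORIES = ("K4_only", "bivalent", "K27_only", "ub_only",
                    "K27_and_ub", "unmarked")

SIGNIFICANCE_TIERS = ((1e-4, "*"), (0.05, "+"))

# Relative tolerance when comparing table probabilities for the two-tailed
# sum; guards against float noise in "equal probability" tables.
_TIE_RTOL = 1e-12


@dataclass
class PromoterState:
    gene: str
    k4me3: bool
    k27me3: bool
    h2aub: bool

    @property
    def category(self) -> str:
        return category_from_flags(self.k4me3, self.k27me3, self.h2aub)


def category_from_flags(k4: bool, k27: bool, ub: bool) -> str:
    """Six-way chromatin-state category.  Bivalent = K4 and K27, regardless
    of H2AK119ub; among K4-negative promoters K27/ub combinations split into
    K27_only, ub_only and K27_and_ub."""
    if k4 and k27:
        return "bivalent"
    if k4:
        return "K4_only"
    if k27 and ub:
        return "K27_and_ub"
    if k27:
        return "K27_only"
    if ub:
        return "ub_only"
    return "unmarked"


def _overlaps_any(chrom: str, start: int, end: int, peaks: pd.DataFrame,
                  min_overlap: int = 1) -> bool:
    sub = peaks[peaks["chrom"] == chrom]
    if sub.empty:
        return False
    ov = (np.minimum(sub["end"].to_numpy(), end)
          - np.maximum(sub["start"].to_numpy(), start))
    return bool((ov >= min_overlap).any())


def promoter_state(gene: str, promoter: tuple[str, int, int],
                   k4_peaks: pd.DataFrame, k27_peaks: pd.DataFrame,
                   ub_peaks: pd.DataFrame, min_overlap: int = 1) -> PromoterState:
    """State of one promoter: a mark flag is set iff >= min_overlap bp of the
    promoter interval is covered by that mark's peaks."""
    chrom, start, end = promoter
    return PromoterState(
        gene,
        _overlaps_any(chrom, start, end, k4_peaks, min_overlap),
        _overlaps_any(chrom, start, end, k27_peaks, min_overlap),
        _overlaps_any(chrom, start, end, ub_peaks, min_overlap),
    )


def promoter_states_table(genes: pd.DataFrame, chrom_lengths: dict[str, int],
                          k4_peaks: pd.DataFrame, k27_peaks: pd.DataFrame,
                          ub_peaks: pd.DataFrame, up: int = 1000,
                          down: int = 1000, min_overlap: int = 1) -> pd.DataFrame:
    """Chromatin state for every gene's promoter."""
    from .annotation import promoter_interval

    rows = []
    for _, g in genes.iterrows():
        s, e = promoter_interval(g, up, down, chrom_lengths.get(g["chrom"]))
        st = promoter_state(g["name"], (g["chrom"], s, e), k4_peaks, k27_peaks,
                            ub_peaks, min_overlap)
        rows.append((st.gene, st.k4me3, st.k27me3, st.h2aub, st.category))
    return pd.DataFrame(rows, columns=["gene", "k4me3", "k27me3", "h2aub",
                                       "category"])


def fisher_two_tailed(table) -> float:
    """Two-tailed Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Probability-mass convention: sum of hypergeometric probabilities, over
    all tables with the observed margins, that do not exceed the observed
    table's probability.  A zero margin yields p = 1 with a warning.
    """
    (a, b), (c, d) = table
    a, b, c, d = int(a), int(b), int(c), int(d)
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be non-negative")
    n = a + b + c + d
    row1, col1 = a + b, a + c
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        warnings.warn("degenerate margin in contingency table; p = 1",
                      stacklevel=2)
        return 1.0
    support = np.arange(max(0, row1 + col1 - n), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = stats.hypergeom.pmf(a, n, row1, col1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum()))


def ease_adjust(table) -> list[list[int]]:
    """EASE adjustment: move one gene out of the overlap cell (a -> a-1,
    b -> b+1), floored so an empty overlap is left unchanged."""
    (a, b), (c, d) = table
    if a > 0:
        return [[a - 1, b + 1], [c, d]]
    return [[a, b], [c, d]]


def ease_adjust_and_test(table) -> tuple[list[list[int]], float]:
    """EASE-adjusted two-tailed Fisher test; conservative for enrichment of
    small overlaps (adjusted p >= raw p on the enrichment side)."""
    adjusted = ease_adjust(table)
    return adjusted, fisher_two_tailed(adjusted)


def _tier(p: float) -> str:
    for threshold, marker in SIGNIFICANCE_TIERS:
        if p < threshold:
            return marker
    return ""


def _one_enrichment(n_in_called: int, n_in: int, n_called: int, n_universe: int,
                    category: str) -> dict:
    table = [[n_in_called, n_in - n_in_called],
             [n_called - n_in_called, n_universe - n_in - n_called + n_in_called]]
    observed = n_in_called / n_called if n_called else np.nan
    expected = n_in / n_universe if n_universe else np.nan
    _, p_ease = ease_adjust_and_test(table)
    p_raw = fisher_two_tailed(table)
    fold = observed / expected if expected else np.nan
    return {
        "category": category,
        "n_called_in_category": n_in_called,
        "n_category": n_in,
        "n_called": n_called,
        "n_universe": n_universe,
        "observed_proportion": observed,
        "expected_proportion": expected,
        "fold": fold,
        # both readings of "percent difference": percentage points and relative
        "percent_point_difference": 100 * (observed - expected),
        "relative_percent_difference": 100 * (observed - expected) / expected
        if expected else np.nan,
        "p_raw": p_raw,
        "p_ease": p_ease,
        "direction": "over" if observed >= expected else "under",
        "tier": _tier(p_ease),
    }


def state_enrichment(calls, states: pd.DataFrame, universe) -> pd.DataFrame:
    """Over/under-representation of each chromatin-state category among
    called genes, against the category's prevalence in the universe.

    ``calls`` must be a subset of ``universe``; ``states`` maps gene ->
    category (columns gene, category).  Empty calls yield an
    ``undefined``-flagged table.
    """
    universe = set(universe)
    calls = set(calls)
    if not calls <= universe:
        raise ValueError("calls must be a subset of the universe")
    cat = states.set_index("gene")["category"]
    rows = []
    for category in STATE_CATEGORIES:
        in_cat = {g for g in universe if cat.get(g) == category}
        if not calls:
            rows.append({"category": category, "undefined": True})
            continue
        res = _one_enrichment(len(in_cat & calls), len(in_cat), len(calls),
                              len(universe), category)
        res["undefined"] = False
        rows.append(res)
    return pd.DataFrame(rows)


def set_overlaps(gene_sets: dict[str, set], universe_size: int) -> dict:
    """All intersection cardinalities (up to 4 sets) and pairwise
    EASE-adjusted Fisher p-values against a common universe."""
    names = list(gene_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets")
    if len(names) > 4:
        raise ValueError("at most four sets supported")
    union = set().union(*gene_sets.values())
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of the sets")
    intersections = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inter = set.intersection(*(set(gene_sets[n]) for n in combo))
            intersections["&".join(combo)] = len(inter)
    rows = []
    for x, y in itertools.combinations(names, 2):
        sx, sy = set(gene_sets[x]), set(gene_sets[y])
        a = len(sx & sy)
        table = [[a, len(sx) - a],
                 [len(sy) - a, universe_size - len(sx) - len(sy) + a]]
        _, p = ease_adjust_and_test(table)
        rows.append((x, y, a, p))
    pairwise = pd.DataFrame(rows, columns=["set_a", "set_b", "intersection",
                                           "p_ease"])
    return {"intersections": intersections, "pairwise": pairwise}


def external_list_comparison(calls_by_condition: dict[str, set],
                             gene_list, universe_size: int = 23218
                             ) -> pd.DataFrame:
    """Per-condition enrichment of calls in an external gene list.

    Reports the percentage of each call set found in the list, the baseline
    percentage (list size / universe), fold, and the EASE-adjusted two-tailed
    Fisher p with tier markers at 1e-4 and 1e-3.
    """
    gene_list = set(gene_list)
    if not gene_list:
        raise ValueError("gene list is empty")
    baseline = 100.0 * len(gene_list) / universe_size
    rows = []
    for condition, calls in calls_by_condition.items():
        calls = set(calls)
        a = len(calls & gene_list)
        n_called = len(calls)
        table = [[a, len(gene_list) - a],
                 [n_called - a, universe_size - len(gene_list) - n_called + a]]
        _, p = ease_adjust_and_test(table)
        pct = 100.0 * a / n_called if n_called else np.nan
        tier = "*" if p < 1e-4 else ("+" if p < 1e-3 else "")
        rows.append((condition, n_called, a, pct, baseline,
                     pct / baseline if baseline else np.nan, p,
                     "over" if pct >= baseline else "under", tier))
    return pd.DataFrame(rows, columns=[
        "condition", "n_called", "n_in_list", "percent_in_list",
        "baseline_percent", "fold", "p_ease", "direction", "tier"])
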