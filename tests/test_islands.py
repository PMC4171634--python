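"""Island caller: deduplication, window statistics, aggregation,
E-value thresholding and differential-region testing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcrosstalk.core import TagLibrary
from methcrosstalk.islands import (CallerParams, aggregate_islands,
                                   background_lambda, call_differential,
                                   call_islands, deduplicate_tags,
                                   eligible_windows, merge_intervals,
                                   score_threshold_for_evalue, tag_midpoints,
                                   window_counts, window_scores)
from methcrosstalk.synthetic import (simulate_planted_differential,
                                     simulate_planted_domains)


def _lib(chroms, positions, strands=None):
    n = len(positions)
    strands = strands or ["+"] * n
    return TagLibrary("test", pd.DataFrame({
        "chrom": chroms if isinstance(chroms, list) else [chroms] * n,
        "pos": positions, "strand": strands}))


class TestDeduplicate:
    def test_stack_of_five_collapses_to_one(self):
        lib = _lib("chr1", [100] * 5)
        assert deduplicate_tags(lib, 1).size == 1

    def test_unique_positions_unchanged(self):
        lib = _lib("chr1", list(range(100)))
        out = deduplicate_tags(lib, 1)
        assert out.tags.equals(lib.tags)

    def test_hand_counted_triples_with_redundancy_two(self, rng):
        # 700 unique positions + 100 positions duplicated as triples = 1000
        # tags; redundancy 2 keeps two of each triple -> 1000 - 100
        unique = list(range(0, 70_000, 100))
        triples = [100_000 + 10 * i for i in range(100)]
        positions = unique + [p for p in triples for _ in range(3)]
        lib = _lib("chr1", positions)
        assert lib.size == 1000
        assert deduplicate_tags(lib, 2).size == 900

    def test_strand_is_part_of_position_identity(self):
        lib = _lib("chr1", [100, 100], strands=["+", "-"])
        assert deduplicate_tags(lib, 1).size == 2


class TestMidpoints:
    def test_plus_strand_extends_right(self):
        lib = _lib("chr1", [1000])
        mids = tag_midpoints(lib, 300, {"chr1": 10_000})
        assert mids["chr1"].tolist() == [1150]

    def test_minus_strand_extends_left(self):
        lib = _lib("chr1", [1000], strands=["-"])
        mids = tag_midpoints(lib, 300, {"chr1": 10_000})
        assert mids["chr1"].tolist() == [850]

    def test_midpoints_clipped_to_chromosome(self, rng):
        pos = rng.integers(0, 1000, size=200)
        strands = list(np.where(rng.random(200) < 0.5, "+", "-"))
        mids = tag_midpoints(_lib("chr1", pos.tolist(), strands), 5000,
                             {"chr1": 1000})
        assert mids["chr1"].min() >= 0
        assert mids["chr1"].max() < 1000


class TestWindowCounts:
    def test_half_open_boundary(self):
        counts = window_counts({"chr1": np.array([0, 199, 200])},
                               {"chr1": 400}, 200)
        assert counts["chr1"].tolist() == [2, 1]

    def test_empty_library_all_zero(self):
        counts = window_counts({}, {"chr1": 1000}, 200)
        assert counts["chr1"].sum() == 0

    def test_conservation(self, rng):
        mids = {"chr1": np.sort(rng.integers(0, 100_000, size=10_000))}
        counts = window_counts(mids, {"chr1": 100_000}, 200)
        assert counts["chr1"].sum() == 10_000


class TestEligibility:
    def test_zero_count_never_eligible(self):
        params = CallerParams()
        masks, _, _ = eligible_windows({"chr1": np.zeros(100, dtype=int)},
                                       1000, {"chr1": 20_000}, params)
        assert not masks["chr1"].any()

    def test_tail_probability_matches_direct_summation(self):
        """Upper-tail Poisson probabilities agree with brute-force summation
        of the pmf to 1e-10 for lambda <= 10, count <= 50."""
        for lam in (0.1, 0.25, 1.0, 3.7, 10.0):
            for count in range(0, 51):
                # stable iterative tail summation of the pmf
                term = math.exp(-lam)
                for k in range(1, count + 1):
                    term *= lam / k
                direct, k = 0.0, count
                while term > 1e-25 or k < count + 20:
                    direct += term
                    k += 1
                    term *= lam / k
                assert abs(stats.poisson.sf(count - 1, lam) - direct) < 1e-10

    def test_explicit_tail_value(self):
        # P(X >= 3; 0.25) = 1 - e^-0.25 (1 + 0.25 + 0.25^2/2)
        lam = 0.25
        expected = 1 - math.exp(-lam) * (1 + lam + lam**2 / 2)
        assert stats.poisson.sf(2, lam) == pytest.approx(expected, abs=1e-12)

    def test_eligibility_and_score_monotone_in_count(self):
        lam = 0.8
        counts = np.arange(0, 30)
        tails = stats.poisson.sf(counts - 1, lam)
        scores = window_scores(counts, lam)
        assert (np.diff(tails) <= 1e-15).all()
        assert (np.diff(scores) >= -1e-12).all()  # past the mode, increasing


class TestAggregation:
    def _setup(self, eligible_at, n_win=50):
        params = CallerParams()
        counts = np.zeros(n_win, dtype=int)
        counts[eligible_at] = 5
        mask = np.zeros(n_win, dtype=bool)
        mask[eligible_at] = True
        scores = window_scores(counts, 0.25)
        return aggregate_islands({"chr1": mask}, {"chr1": scores},
                                 {"chr1": counts}, params,
                                 {"chr1": n_win * 200})

    def test_gap_above_600_splits(self):
        # windows at 0 and 1000 bp: edge-to-edge gap 800 bp > 600
        islands = self._setup([0, 5])
        assert len(islands) == 2

    def test_gap_of_600_merges(self):
        # windows at 0 and 800 bp: edge-to-edge gap 600 bp
        islands = self._setup([0, 4])
        assert len(islands) == 1
        assert (islands.iloc[0]["start"], islands.iloc[0]["end"]) == (0, 1000)

    def test_island_score_is_sum_of_member_scores(self):
        islands = self._setup([0, 1, 2])
        scores = window_scores(np.array([5]), 0.25)
        assert islands.iloc[0]["score"] == pytest.approx(3 * scores[0])

    def test_planted_domains_recovered(self):
        """>= 45/50 planted 2-kb domains at 8x background are each covered
        >= 50% by a called island, at default parameters."""
        for seed in (0, 1):
            lib, domains = simulate_planted_domains(seed=seed)
            chrom_lengths = {f"chr{i+1}": 2_000_000 for i in range(3)}
            islands = call_islands(lib, chrom_lengths)
            recovered = 0
            for _, d in domains.iterrows():
                sub = islands[islands["chrom"] == d["chrom"]]
                ov = (np.minimum(sub["end"], d["end"])
                      - np.maximum(sub["start"], d["start"])).clip(lower=0)
                if ov.sum() >= 0.5 * (d["end"] - d["start"]):
                    recovered += 1
            assert recovered >= 45

    def test_island_set_invariant_to_tag_order(self, rng):
        lib, _ = simulate_planted_domains(seed=3, n_domains=10,
                                          genome_length=1_200_000,
                                          n_chromosomes=1,
                                          background_tags=3000)
        chrom_lengths = {"chr1": 1_200_000}
        shuffled = TagLibrary("test", lib.tags.sample(frac=1, random_state=7))
        a = call_islands(lib, chrom_lengths)
        b = call_islands(shuffled, chrom_lengths)
        pd.testing.assert_frame_equal(a, b)


class TestScoreThreshold:
    def test_infinite_evalue_disables_filtering(self):
        params = CallerParams(e_value=np.inf)
        assert score_threshold_for_evalue(params, 0.5, {"chr1": 1_000_000}) == 0.0

    def test_threshold_nonincreasing_in_evalue(self):
        lengths = {"chr1": 2_000_000}
        thresholds = [
            score_threshold_for_evalue(CallerParams(e_value=e), 0.5, lengths)
            for e in (10, 50, 200, 1000)
        ]
        assert all(a >= b for a, b in zip(thresholds, thresholds[1:]))

    def test_null_calibration(self):
        """On fresh pure-background genomes the number of islands passing the
        returned threshold stays within 2x the E-value in >= 95% of 20
        replicates."""
        params = CallerParams(e_value=50)
        lengths = {"chr1": 6_000_000}
        lam = 0.5
        threshold = score_threshold_for_evalue(params, lam, lengths)
        assert threshold > 0  # the null produces more than 50 islands
        rng = np.random.default_rng(424242)
        n_windows = 30_000
        ok = 0
        for _ in range(20):
            c = rng.poisson(lam, n_windows)
            tail = stats.poisson.sf(c - 1, lam)
            mask = tail < params.window_pvalue
            sc = window_scores(c, lam)
            islands = aggregate_islands({"chr1": mask}, {"chr1": sc},
                                        {"chr1": c}, params,
                                        {"chr1": 6_000_000}, threshold)
            if len(islands) <= 2 * params.e_value:
                ok += 1
        assert ok >= 19


def _bh_oracle(p):
    """Independent sort-based Benjamini-Hochberg implementation."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestDifferential:
    def test_bh_matches_sort_based_oracle(self, rng):
        from statsmodels.stats.multitest import multipletests

        for n in (1, 10, 500, 1000):
            p = rng.random(n)
            np.testing.assert_allclose(multipletests(p, method="fdr_bh")[1],
                                       _bh_oracle(p), atol=1e-12)

    def test_identical_libraries_yield_null(self):
        islands, lib_a, _, _, chrom_lengths = simulate_planted_differential(
            n_islands=200, depth=100_000, seed=5)
        diff = call_differential(islands, lib_a, lib_a, chrom_lengths)
        assert (diff["log2_fold_change"].abs() < 0.1).all()
        assert diff["significant"].sum() == 0

    def test_planted_fourfold_regions_recovered(self):
        islands, lib_a, lib_b, diff_idx, chrom_lengths = (
            simulate_planted_differential(seed=2))
        diff = call_differential(islands, lib_a, lib_b, chrom_lengths)
        recovered = diff.loc[diff_idx, "significant"].sum()
        assert recovered >= 27
        # and the planted regions show ~ 4-fold enrichment
        assert diff.loc[diff_idx, "log2_fold_change"].median() == pytest.approx(
            2.0, abs=0.3)

    def test_swapping_libraries_negates_fold_change_exactly(self):
        islands, lib_a, lib_b, _, chrom_lengths = (
            simulate_planted_differential(n_islands=100, depth=50_000, seed=9))
        ab = call_differential(islands, lib_a, lib_b, chrom_lengths)
        ba = call_differential(islands, lib_b, lib_a, chrom_lengths)
        np.testing.assert_array_equal(ab["log2_fold_change"].to_numpy(),
                                      -ba["log2_fold_change"].to_numpy())

    def test_empty_island_union_is_empty_result(self):
        lib = _lib("chr1", [100, 200])
        empty = pd.DataFrame(columns=["chrom", "start", "end"])
        out = call_differential(empty, lib, lib, {"chr1": 1000})
        assert len(out) == 0


class TestEndToEndDeterminism:
    def test_same_inputs_same_outputs(self):
        lib, _ = simulate_planted_domains(seed=4, n_domains=10,
                                          genome_length=1_200_000,
                                          n_chromosomes=1,
                                          background_tags=3000)
        chrom_lengths = {"chr1": 1_200_000}
        a = call_islands(lib, chrom_lengths)
        b = call_islands(lib, chrom_lengths)
        pd.testing.assert_frame_equal(a, b)

    def test_window_count_conservation_per_chromosome(self, control_library,
                                                      annotation):
        mids = tag_midpoints(control_library, 300, annotation.chrom_lengths)
        counts = window_counts(mids, annotation.chrom_lengths, 200)
        for chrom, m in mids.items():
            assert counts[chrom].sum() == m.size

    def test_called_islands_do_not_overlap(self, control_library, annotation):
        islands = call_islands(control_library, annotation.chrom_lengths)
        for _, sub in islands.groupby("chrom"):
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()
            assert ((ends - starts) % 200 == 0).all()
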