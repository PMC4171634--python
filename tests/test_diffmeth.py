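"""Hyper/hypo calling, rollup, clustering and validation-assay arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methcrosstalk.core import GenomeAnnotation
from methcrosstalk.diffmeth import (build_call_matrix, call_feature_status,
                                    feature_log2_change, gene_level_rollup,
                                    hierarchical_cluster, infinium_diff,
                                    infinium_promoter_rollup,
                                    medip_enrichment)


class TestLog2Change:
    def test_fourfold(self):
        assert feature_log2_change(4.0, 1.0, 1e-12) == pytest.approx(2.0)

    def test_equal_inputs_zero(self):
        assert feature_log2_change(3.3, 3.3, 0.5) == 0.0

    def test_zero_vs_zero_guarded(self):
        assert feature_log2_change(0.0, 0.0, 0.1) == 0.0

    @given(st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_antisymmetric_under_swap(self, a, b):
        c = 0.25
        assert feature_log2_change(a, b, c) == pytest.approx(
            -feature_log2_change(b, a, c))


class TestStatus:
    @pytest.mark.parametrize("x,expected", [
        (1.0, "hyper"),      # 2-fold-or-greater boundary is inclusive
        (-0.99, "unchanged"),
        (-1.5, "hypo"),
        (0.0, "unchanged"),
        (-1.0, "hypo"),
    ])
    def test_boundaries(self, x, expected):
        assert call_feature_status(x) == expected

    @given(st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_mirror_symmetry(self, x):
        flip = {"hyper": "hypo", "hypo": "hyper", "unchanged": "unchanged"}
        assert call_feature_status(-x) == flip[call_feature_status(x)]

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            call_feature_status(0.5, fold_threshold=1.0)


def _toy_annotation():
    genes = pd.DataFrame({
        "name": ["geneA", "geneB"], "chrom": ["chr1", "chr1"],
        "strand": ["+", "+"], "tx_start": [10_000, 50_000],
        "tx_end": [30_000, 70_000]})
    cgis = pd.DataFrame({"chrom": ["chr1"], "start": [9500], "end": [10_500],
                         "name": ["cgiA"]})
    return GenomeAnnotation({"chr1": 100_000}, genes, cgis)


def _region(start, end, l2fc):
    return {"chrom": "chr1", "start": start, "end": end,
            "log2_fold_change": l2fc, "significant": True}


class TestRollup:
    def test_hyper_promoter_region(self):
        annot = _toy_annotation()
        regions = pd.DataFrame([_region(9400, 9800, 1.5)])
        calls = gene_level_rollup(regions, annot, "kd")
        prom = calls[calls["feature_class"] == "promoter"]
        assert list(prom["gene"]) == ["geneA"]
        assert list(prom["status"]) == ["hyper"]
        # the region also overlaps the promoter CGI and its shore
        assert set(calls["feature_class"]) >= {"promoter", "cgi"}

    def test_gene_with_hyper_and_hypo_body_regions_keeps_both(self):
        annot = _toy_annotation()
        regions = pd.DataFrame([_region(15_000, 16_000, 2.0),
                                _region(25_000, 26_000, -2.0)])
        calls = gene_level_rollup(regions, annot, "kd")
        body = calls[(calls["feature_class"] == "body")
                     & (calls["gene"] == "geneA")]
        assert set(body["status"]) == {"hyper", "hypo"}

    def test_subthreshold_regions_ignored(self):
        annot = _toy_annotation()
        regions = pd.DataFrame([_region(15_000, 16_000, 0.8)])
        assert gene_level_rollup(regions, annot, "kd").empty

    def test_region_order_invariance(self):
        annot = _toy_annotation()
        regions = pd.DataFrame([_region(15_000, 16_000, 2.0),
                                _region(55_000, 56_000, 1.4),
                                _region(9400, 9800, -1.2)])
        a = gene_level_rollup(regions, annot, "kd")
        b = gene_level_rollup(regions.iloc[::-1].reset_index(drop=True),
                              annot, "kd")
        pd.testing.assert_frame_equal(
            a.sort_values(list(a.columns)).reset_index(drop=True),
            b.sort_values(list(b.columns)).reset_index(drop=True))


class TestCallMatrix:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["gene", "feature_class",
                                           "condition", "log2_change",
                                           "status"])

    def test_single_condition_single_cell(self):
        calls = self._calls([("g1", "promoter", "kdA", 1.5, "hyper")])
        mat = build_call_matrix(calls)
        assert mat.shape == (1, 1)
        assert mat.loc["g1", "kdA"] == 1.5

    def test_no_differential_genes_empty(self):
        calls = self._calls([("g1", "promoter", "kdA", 0.1, "unchanged")])
        assert build_call_matrix(calls).empty

    def test_rows_are_union_of_per_condition_sets(self):
        calls = self._calls([
            ("g1", "promoter", "kdA", 1.5, "hyper"),
            ("g2", "promoter", "kdB", -1.5, "hypo"),
            ("g1", "promoter", "kdB", 1.2, "hyper"),
            ("g3", "body", "kdA", 2.0, "hyper"),  # other feature class
        ])
        mat = build_call_matrix(calls, "promoter")
        assert set(mat.index) == {"g1", "g2"}
        assert mat.loc["g2", "kdA"] == 0.0  # unchanged cell filled with 0


class TestClustering:
    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, -3.0]],
                           index=["a", "b", "c"], columns=["x", "y"])
        res = hierarchical_cluster(mat)
        first_merge = res["row_linkage"][0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == 0.0

    def test_block_matrix_top_split_separates_signs(self, rng):
        up = rng.normal(2.0, 0.2, size=(10, 4))
        down = rng.normal(-2.0, 0.2, size=(10, 4))
        mat = pd.DataFrame(np.vstack([up, down]),
                           index=[f"u{i}" for i in range(10)]
                           + [f"d{i}" for i in range(10)])
        res = hierarchical_cluster(mat)
        order = res["row_order"]
        groups = ["".join(g[0]) for g in order]
        # leaves of each sign are contiguous after ordering
        assert sorted(set(groups[:10])) in (["u"], ["d"])
        assert len(set(groups[:10])) == 1 and len(set(groups[10:])) == 1

    def test_row_permutation_leaves_topology_unchanged(self, rng):
        mat = pd.DataFrame(rng.normal(size=(12, 3)),
                           index=[f"g{i}" for i in range(12)])
        perm = mat.sample(frac=1, random_state=3)
        a = hierarchical_cluster(mat)
        b = hierarchical_cluster(perm)
        # same partition at the top split
        def top_split(res, matrix):
            from scipy.cluster import hierarchy
            labels = hierarchy.fcluster(res["row_linkage"], 2, "maxclust")
            groups = {}
            for name, lab in zip(matrix.index, labels):
                groups.setdefault(lab, set()).add(name)
            return frozenset(frozenset(v) for v in groups.values())
        assert top_split(a, mat) == top_split(b, perm)

    def test_constant_matrix_warns(self):
        mat = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        with pytest.warns(UserWarning, match="constant"):
            hierarchical_cluster(mat)


class TestInfinium:
    def _betas(self, means, sd, reps, rng):
        return pd.DataFrame(
            np.clip(rng.normal(np.repeat(np.asarray(means)[:, None], reps,
                                         axis=1), sd), 0, 1),
            index=[f"p{i}" for i in range(len(means))])

    def test_large_delta_small_p_is_hyper(self, rng):
        kd = self._betas([0.6] * 5, 0.01, 4, rng)
        ctrl = self._betas([0.3] * 5, 0.01, 4, rng)
        calls = infinium_diff(kd, ctrl)
        assert (calls["status"] == "hyper").all()

    def test_large_delta_large_p_is_unchanged(self):
        # delta 0.25 but within-arm scatter so wide that p > 0.05
        kd = pd.DataFrame([[0.05, 0.95, 0.1, 0.9]], index=["p0"])
        ctrl = pd.DataFrame([[0.9, 0.05, 0.95, 0.1]], index=["p0"])
        calls = infinium_diff(kd, ctrl)
        assert calls["status"].iloc[0] == "unchanged"
        assert calls["p_value"].iloc[0] > 0.05

    def test_noiseless_planted_delta_all_called(self):
        kd = pd.DataFrame(np.full((20, 4), 0.5), index=range(20))
        ctrl = pd.DataFrame(np.full((20, 4), 0.2), index=range(20))
        calls = infinium_diff(kd, ctrl)
        assert (calls["status"] == "hyper").all()

    def test_mismatched_probes_rejected(self):
        kd = pd.DataFrame(np.zeros((2, 2)), index=["a", "b"])
        ctrl = pd.DataFrame(np.zeros((2, 2)), index=["a", "c"])
        with pytest.raises(ValueError):
            infinium_diff(kd, ctrl)

    def test_single_replicate_degrades_to_delta_only(self):
        kd = pd.DataFrame([[0.6], [0.3]], index=["a", "b"])
        ctrl = pd.DataFrame([[0.2], [0.25]], index=["a", "b"])
        calls = infinium_diff(kd, ctrl)
        assert (calls["test"] == "delta_only").all()
        assert calls.set_index("probe").loc["a", "status"] == "hyper"
        assert calls.set_index("probe").loc["b", "status"] == "unchanged"


class TestInfiniumRollup:
    def _genes(self):
        return pd.DataFrame({"name": ["gA"], "chrom": ["chr1"],
                             "strand": ["+"], "tx_start": [10_000],
                             "tx_end": [20_000]})

    def test_probe_in_window_called(self):
        calls = pd.DataFrame({"probe": ["p1"], "status": ["hyper"]})
        pmap = pd.DataFrame({"probe": ["p1"], "chrom": ["chr1"],
                             "pos": [9500], "gene": ["gA"]})
        out = infinium_promoter_rollup(calls, pmap, self._genes())
        assert list(out.itertuples(index=False))[0][:2] == ("gA", "hyper")

    def test_probe_downstream_of_tss_not_counted(self):
        calls = pd.DataFrame({"probe": ["p1"], "status": ["hyper"]})
        pmap = pd.DataFrame({"probe": ["p1"], "chrom": ["chr1"],
                             "pos": [10_010], "gene": ["gA"]})
        assert infinium_promoter_rollup(calls, pmap, self._genes()).empty


class TestMedip:
    @pytest.mark.parametrize("sample,inp,expected", [
        (25.0, 25.0, 1.0),
        (23.0, 25.0, 4.0),   # delta Ct of -2 -> 2^2
        (26.0, 25.0, 0.5),
    ])
    def test_enrichment_formula(self, sample, inp, expected):
        assert medip_enrichment(sample, inp) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            medip_enrichment(np.nan, 25.0)


class TestSeqArrayConcordance:
    def test_capture_and_array_calls_agree_on_detectable_planted_genes(
            self, annotation, truth, control_library, kd_library, sim_config):
        """Genes with planted promoter hypermethylation that the capture
        assay can see (CGI promoters; CpG-poor promoters yield too few
        capture fragments to test) are called hyper by both the sequencing
        rollup and the array rollup in >= 80% of cases."""
        from methcrosstalk import simulate_infinium
        from methcrosstalk.diffmeth import feature_differential

        diff = feature_differential(kd_library, control_library, annotation)
        seq_calls = gene_level_rollup(diff, annotation, "siKD")
        seq_hyper = set(seq_calls[(seq_calls["feature_class"] == "promoter")
                                  & (seq_calls["status"] == "hyper")]["gene"])

        beta, pmap = simulate_infinium(truth, annotation, sim_config)
        arr_calls = infinium_diff(beta["siKD"], beta["control"])
        arr_roll = infinium_promoter_rollup(arr_calls, pmap, annotation.genes)
        arr_hyper = set(arr_roll[arr_roll["status"] == "hyper"]["gene"])

        planted = set(truth.planted[
            truth.planted["feature_class"] == "promoter"]["gene"])
        cgi_prom = {n.split("cgi_prom_")[1] for n in annotation.cgis["name"]
                    if n.startswith("cgi_prom_")}
        detectable = planted & cgi_prom
        assert len(detectable) >= 20
        agree = sum(1 for g in detectable
                    if (g in seq_hyper) and (g in arr_hyper))
        assert agree / len(detectable) >= 0.8
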