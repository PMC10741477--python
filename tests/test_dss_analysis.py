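"""sDSS, responder filtering, correlation, F-tests, ΔDSS/ΔSD, clustering, PCA."""

import math

import numpy as np
import pandas as pd
import pytest

from gscdsrt import dss_analysis as da


class TestSDSS:
    def test_hand_computed_toy(self):
        # reference DSS (12, 8, 10): mean 10; test culture at 15 → sDSS 5
        mat = pd.DataFrame({"d": [12.0, 8.0, 10.0, 15.0]},
                           index=["r1", "r2", "r3", "t"])
        out = da.sdss(mat, ["r1", "r2", "r3"])
        assert out.loc["t", "d"] == pytest.approx(5.0)

    def test_reference_centering_identity(self, grouped_dss_matrix):
        out = da.sdss(grouped_dss_matrix, list(grouped_dss_matrix.index))
        assert np.allclose(out.sum(axis=0), 0.0, atol=1e-10)

    def test_culture_at_reference_mean_scores_zero(self):
        mat = pd.DataFrame({"d1": [5.0, 15.0, 10.0], "d2": [0.0, 4.0, 2.0]},
                           index=["r1", "r2", "t"])
        out = da.sdss(mat, ["r1", "r2"])
        assert np.allclose(out.loc["t"], 0.0)

    def test_reference_mean_skips_missing(self):
        mat = pd.DataFrame({"d": [12.0, np.nan, 8.0, 15.0]},
                           index=["r1", "r2", "r3", "t"])
        out = da.sdss(mat, ["r1", "r2", "r3"])
        assert out.loc["t", "d"] == pytest.approx(5.0)

    def test_empty_reference_rejected(self):
        mat = pd.DataFrame({"d": [1.0]}, index=["c"])
        with pytest.raises(ValueError):
            da.sdss(mat, [])


class TestFilterResponders:
    def test_boundary_is_inclusive(self):
        mat = pd.DataFrame(np.zeros((3, 3)), columns=["a", "b", "c"])
        mat.iloc[1, 1] = 10.0
        assert da.filter_responders(mat, 10.0) == ["b"]

    def test_all_zero_gives_empty_set(self):
        mat = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        assert da.filter_responders(mat, 10.0) == []

    def test_vacuous_threshold_returns_all(self):
        mat = pd.DataFrame(np.zeros((2, 2)), columns=["a", "b"])
        assert da.filter_responders(mat, -np.inf) == ["a", "b"]

    def test_per_culture_counts(self):
        mat = pd.DataFrame([[12.0, 0.0], [11.0, 15.0]], index=["c1", "c2"],
                           columns=["a", "b"])
        counts = da.filter_responders(mat, 10.0, scope="per_culture")
        assert counts.tolist() == [1, 2]


class TestCorrelation:
    def test_duplicated_culture_perfect_correlation(self):
        mat = pd.DataFrame([[1.0, 5, 3, 9], [1.0, 5, 3, 9]], index=["a", "b"],
                           columns=list("wxyz"))
        corr, _ = da.correlation_matrix(mat)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_rank_reversal_is_minus_one(self):
        mat = pd.DataFrame([[1.0, 2, 3, 4], [4.0, 3, 2, 1]], index=["a", "b"],
                           columns=list("wxyz"))
        corr, _ = da.correlation_matrix(mat)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_spearman_formula_toy(self):
        # ranks (1,2,3,4) vs (1,2,4,3): ρ = 1 − 6·2/(4·15) = 0.8
        mat = pd.DataFrame([[1.0, 2, 3, 4], [1.0, 2, 4, 3]], index=["a", "b"],
                           columns=list("wxyz"))
        corr, summary = da.correlation_matrix(mat)
        assert corr.loc["a", "b"] == pytest.approx(0.8)
        assert summary["mean"] == pytest.approx(0.8)

    def test_insufficient_shared_drugs_warns_and_leaves_missing(self):
        mat = pd.DataFrame([[1.0, 2, np.nan, np.nan], [np.nan, np.nan, 1.0, 2]],
                           index=["a", "b"], columns=list("wxyz"))
        with pytest.warns(UserWarning, match="shared"):
            corr, _ = da.correlation_matrix(mat)
        assert np.isnan(corr.loc["a", "b"])


class TestVarianceFTests:
    def test_closed_form_f11_toy(self):
        # var(0,10)=50 vs var(4,6)=2: F=25, df (1,1); the F(1,1) upper tail
        # is 1 − (2/π)·arctan(√F)
        mat = pd.DataFrame({"d": [0.0, 10.0, 4.0, 6.0]},
                           index=["a1", "a2", "b1", "b2"])
        res = da.variance_f_tests(mat, ["a1", "a2"], ["b1", "b2"])
        row = res.iloc[0]
        assert row["f_stat"] == pytest.approx(25.0)
        assert row["p_one_sided"] == pytest.approx(1 - 2 / math.pi * math.atan(5.0),
                                                   rel=1e-9)

    def test_zero_intra_variance_gives_zero_p(self):
        mat = pd.DataFrame({"d": [0.0, 10.0, 5.0, 5.0]},
                           index=["a1", "a2", "b1", "b2"])
        res = da.variance_f_tests(mat, ["a1", "a2"], ["b1", "b2"])
        assert np.isinf(res.iloc[0]["f_stat"])
        assert res.iloc[0]["p_one_sided"] == 0.0

    def test_degenerate_drug_skipped(self):
        mat = pd.DataFrame({"d": [5.0, 5.0, 5.0, 5.0]},
                           index=["a1", "a2", "b1", "b2"])
        res = da.variance_f_tests(mat, ["a1", "a2"], ["b1", "b2"])
        assert res.empty
        assert res.attrs["skipped"] == [("d", "both_variances_zero")]

    def test_fdr_adjusted_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(0)
        mat = pd.DataFrame(rng.normal(10, 3, (8, 30)),
                           index=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
                           columns=[f"d{i}" for i in range(30)])
        res = da.variance_f_tests(mat, [f"a{i}" for i in range(4)],
                                  [f"b{i}" for i in range(4)])
        assert (res["p_fdr"] >= res["p_one_sided"] - 1e-15).all()
        s = res.sort_values("p_one_sided")
        assert s["p_fdr"].is_monotonic_increasing

    def test_null_calibration_small(self):
        """Type-I error of the one-sided test ≈ α on null data (quick check;
        the full 115×1000 calibration runs in the acceptance suite)."""
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, (300, 50, 14)).var(axis=2, ddof=1)
        b = rng.normal(0, 1, (300, 50, 7)).var(axis=2, ddof=1)
        _, p = da.f_test_upper(a, b, 13, 6)
        assert (p < 0.05).mean() == pytest.approx(0.05, abs=0.01)


class TestDeltaAnalysis:
    def test_hand_computed_quadrants(self):
        mat = pd.DataFrame({"d": [20.0, 20, 20, 5, 10, 15]},
                           index=["t1", "t2", "t3", "r1", "r2", "r3"])
        out = da.delta_analysis(mat, ["t1", "t2", "t3"], ["r1", "r2", "r3"])
        row = out.loc["d"]
        assert row["delta_dss"] == pytest.approx(10.0)
        assert row["delta_sd"] == pytest.approx(5.0)
        assert row["quadrant"] == "specific-homogeneous"

    def test_tie_routes_to_nonspecific(self):
        mat = pd.DataFrame({"d": [0.0, 10, 20, 9, 10, 11]},
                           index=["t1", "t2", "t3", "r1", "r2", "r3"])
        out = da.delta_analysis(mat, ["t1", "t2", "t3"], ["r1", "r2", "r3"])
        row = out.loc["d"]
        assert row["delta_dss"] == pytest.approx(0.0)
        assert row["delta_sd"] == pytest.approx(-9.0)
        assert row["quadrant"] == "nonspecific-heterogeneous"

    def test_identical_groups_all_zero(self, grouped_dss_matrix):
        ids = list(grouped_dss_matrix.index[:3])
        out = da.delta_analysis(grouped_dss_matrix, ids, ids)
        assert np.allclose(out["delta_dss"], 0.0)
        assert np.allclose(out["delta_sd"], 0.0)

    def test_group_swap_antisymmetry(self, grouped_dss_matrix):
        mr = [i for i in grouped_dss_matrix.index if i.startswith("MR")]
        ref = [i for i in grouped_dss_matrix.index if i.startswith("REF")]
        fwd = da.delta_analysis(grouped_dss_matrix, mr, ref).sort_index()
        rev = da.delta_analysis(grouped_dss_matrix, ref, mr).sort_index()
        assert np.allclose(fwd["delta_dss"], -rev["delta_dss"])
        assert np.allclose(fwd["delta_sd"], -rev["delta_sd"])

    def test_singleton_group_rejected(self, grouped_dss_matrix):
        with pytest.raises(ValueError):
            da.delta_analysis(grouped_dss_matrix, ["MRa"],
                              ["REFa", "REFb", "REFc"])


class TestClustering:
    def test_one_dimensional_complete_linkage_topology(self):
        # points 0,1,10,11: close pairs merge first → ((0,1),(10,11))
        mat = pd.DataFrame({"v": [0.0, 1.0, 10.0, 11.0]},
                           index=["p00", "p01", "p10", "p11"])
        res = da.cluster_heatmap(mat)
        assert res.row_newick == "((p00:1,p01:1):10,(p10:1,p11:1):10):0;"

    def test_identical_pair_merges_first(self):
        rng = np.random.default_rng(1)
        mat = pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "b", "far"],
                           columns=list("vwxyz"))
        mat.loc["b"] = mat.loc["a"]
        mat.loc["far"] += 50.0
        res = da.cluster_heatmap(mat)
        first_merge = res.row_linkage[0]
        assert {int(first_merge[0]), int(first_merge[1])} == {0, 1}
        assert first_merge[2] == pytest.approx(0.0)

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError, match="constant"):
            da.cluster_heatmap(mat)

    def test_row_order_invariance(self, grouped_dss_matrix):
        res1 = da.cluster_heatmap(grouped_dss_matrix)
        shuffled = grouped_dss_matrix.sample(frac=1.0, random_state=3)
        res2 = da.cluster_heatmap(shuffled)
        assert res1.row_newick == res2.row_newick
        pd.testing.assert_frame_equal(res1.ordered, res2.ordered)

    def test_drug_filter_applied(self, grouped_dss_matrix):
        res = da.cluster_heatmap(grouped_dss_matrix, drug_filter=["d0", "d1"])
        assert list(res.ordered.columns) in ([["d0", "d1"]], [["d1", "d0"]]) or \
            set(res.ordered.columns) == {"d0", "d1"}


class TestPCA:
    def test_two_duplicated_clusters_separate_on_pc1(self):
        mat = pd.DataFrame([[0.0] * 5, [0.0] * 5, [10.0] * 5, [10.0] * 5],
                           index=["a1", "a2", "b1", "b2"],
                           columns=[f"d{i}" for i in range(5)])
        scores, evr = da.pca_view(mat, log_transform=False)
        assert scores.loc["a1", "PC1"] == pytest.approx(scores.loc["a2", "PC1"])
        assert abs(scores.loc["a1", "PC1"] - scores.loc["b1", "PC1"]) > 1.0
        assert evr[0] == pytest.approx(1.0)

    def test_explained_variance_sums_to_one(self, grouped_dss_matrix):
        _, evr = da.pca_view(grouped_dss_matrix, log_transform=True)
        assert evr.sum() == pytest.approx(1.0)

    def test_complete_case_drug_selection(self, grouped_dss_matrix):
        mat = grouped_dss_matrix.copy()
        mat.iloc[0, 0] = np.nan
        scores, _ = da.pca_view(mat, log_transform=False)
        assert scores.attrs["n_drugs_used"] == mat.shape[1] - 1

    def test_negative_values_rejected_with_log(self):
        mat = pd.DataFrame([[-1.0, 2.0], [3.0, 4.0]], index=["a", "b"],
                           columns=["x", "y"])
        with pytest.raises(ValueError, match="negative"):
            da.pca_view(mat, log_transform=True)

    def test_row_order_invariance(self, grouped_dss_matrix):
        s1, _ = da.pca_view(grouped_dss_matrix)
        s2, _ = da.pca_view(grouped_dss_matrix.sample(frac=1.0, random_state=8))
        pd.testing.assert_frame_equal(s1, s2)


class TestClassSummary:
    def test_hand_computed_class_mean(self):
        sdss = pd.DataFrame([[4.0, -2.0]], index=["c"], columns=["d1", "d2"])
        means, counts = da.class_summary(sdss, {"d1": "K", "d2": "K"})
        assert means.loc["c", "K"] == pytest.approx(1.0)
        assert counts["K"] == 2

    def test_unmapped_drugs_fall_into_other(self):
        sdss = pd.DataFrame([[4.0, -2.0]], index=["c"], columns=["d1", "d2"])
        means, counts = da.class_summary(sdss, {"d1": "K"})
        assert means.loc["c", "other"] == pytest.approx(-2.0)

    def test_empty_map_warns(self):
        sdss = pd.DataFrame([[0.0]], index=["c"], columns=["d1"])
        with pytest.warns(UserWarning, match="empty"):
            means, _ = da.class_summary(sdss, {})
        assert means.loc["c", "other"] == 0.0
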