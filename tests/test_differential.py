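import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from quadromics import (
    AbundanceMatrix,
    ComparisonSpec,
    Thresholds,
    call_dams,
    call_degs,
    class_composition,
    feature_test,
    fold_change,
    hca_order,
    impute_zeros,
    run_differential,
    venn_partition,
)
from quadromics.data_io import FeatureAnnotation, SampleDesign


def _matrix(arr, design, ids=None):
    ids = ids or [f"m{i}" for i in range(len(arr))]
    return AbundanceMatrix(
        pd.DataFrame(arr, index=ids, columns=design.sample_ids), design
    )


class TestImputeZeros:
    def test_half_min_positive_rule(self, two_stage_design):
        arr = np.tile([0.0, 4.0, 8.0], (6, 1)).T
        out = impute_zeros(_matrix(arr, two_stage_design))
        assert set(np.unique(out.values.to_numpy())) == {2.0, 4.0, 8.0}

    def test_identity_without_zeros(self, toy_matrix):
        sub = toy_matrix.subset(["m1", "m2", "m3"])
        assert impute_zeros(sub).values.equals(sub.values)

    def test_pseudocount(self, two_stage_design):
        arr = np.tile([0.0, 1.0], (6, 1)).T
        out = impute_zeros(_matrix(arr, two_stage_design), rule="pseudocount", pseudocount=1)
        assert set(np.unique(out.values.to_numpy())) == {1.0, 2.0}

    def test_all_zero_matrix_rejected(self, two_stage_design):
        with pytest.raises(ValueError, match="all zeros"):
            impute_zeros(_matrix(np.zeros((2, 6)), two_stage_design))


class TestFoldChange:
    def test_known_ratios(self, toy_matrix):
        fc = fold_change(impute_zeros(toy_matrix), ComparisonSpec("PEC", "NEC"))
        assert fc.loc["m2", "fc"] == pytest.approx(50 / 5.5)
        assert fc.loc["m1", "log2fc"] == pytest.approx(0.0)

    def test_log2_consistency(self, toy_matrix):
        fc = fold_change(impute_zeros(toy_matrix), ComparisonSpec("PEC", "NEC"))
        np.testing.assert_allclose(fc["log2fc"], np.log2(fc["fc"]))

    def test_antisymmetry(self, toy_matrix):
        imputed = impute_zeros(toy_matrix)
        fwd = fold_change(imputed, ComparisonSpec("PEC", "NEC"))["fc"]
        rev = fold_change(imputed, ComparisonSpec("NEC", "PEC"))["fc"]
        np.testing.assert_allclose(fwd * rev, 1.0)

    def test_zero_reference_mean_rejected(self, two_stage_design):
        arr = np.array([[0, 0, 0, 1, 1, 1.0]])
        with pytest.raises(ValueError, match="impute"):
            fold_change(_matrix(arr, two_stage_design), ComparisonSpec("PEC", "NEC"))


class TestFeatureTest:
    def test_identical_groups_p_one(self, two_stage_design):
        arr = np.array([[3.0, 3, 3, 3, 3, 3]])
        p = feature_test(_matrix(arr, two_stage_design), ComparisonSpec("PEC", "NEC"))
        assert p.iloc[0] == 1.0

    def test_large_shift_tiny_variance(self, two_stage_design):
        """t-distribution tail oracle: huge standardized shift gives p < 0.001."""
        arr = np.array([[1.0, 1.01, 1.02, 101, 102, 103]])
        p = feature_test(_matrix(arr, two_stage_design), ComparisonSpec("PEC", "NEC"))
        a = np.log2(np.array([101.0, 102, 103]) + 1)
        b = np.log2(np.array([1.0, 1.01, 1.02]) + 1)
        oracle = stats.ttest_ind(a, b, equal_var=False).pvalue
        assert p.iloc[0] < 1e-3
        assert p.iloc[0] == pytest.approx(oracle)

    def test_welch_equals_student_when_balanced(self, two_stage_design, rng):
        cmp = ComparisonSpec("PEC", "NEC")
        # group 2 = (group1 + 1) * 16 - 1, so log2(x+1) shifts by exactly 4:
        # equal n and identical group variances on the tested scale
        g1 = rng.lognormal(size=(10, 3))
        sym = np.column_stack([g1, (g1 + 1) * 16 - 1])
        msym = _matrix(sym, two_stage_design)
        pw = feature_test(msym, cmp, test="welch")
        ps = feature_test(msym, cmp, test="student")
        np.testing.assert_allclose(pw, ps, rtol=1e-9)


class TestCallDams:
    @pytest.mark.parametrize(
        "fc,vip,p,expected",
        [
            (2.0, 1.0, 0.01, "up"),        # boundaries inclusive
            (3.0, 0.5, 0.01, "unchanged"),  # VIP filter
            (0.5, 1.2, 0.01, "down"),
            (1.9, 5.0, 0.01, "unchanged"),
            (2.5, 1.5, 0.20, "unchanged"),  # p-filter active by default
        ],
    )
    def test_threshold_rules(self, fc, vip, p, expected):
        status = call_dams(
            pd.Series([fc]), pd.Series([vip]), pd.Series([p]), Thresholds()
        )
        assert status.iloc[0] == expected

    def test_p_filter_disabled(self):
        status = call_dams(
            pd.Series([2.5]), pd.Series([1.5]), None, Thresholds(p_filter=False)
        )
        assert status.iloc[0] == "up"

    def test_statuses_partition_features(self, small_metabolome):
        matrix, _ = small_metabolome
        result = run_differential(matrix, ComparisonSpec("PEC", "NEC"))
        assert result["status"].isin(["up", "down", "unchanged"]).all()
        assert len(result) == matrix.n_features


class TestCallDegs:
    def test_strong_gene_up(self, two_stage_design):
        arr = np.vstack([
            np.array([8.0, 10, 9, 120, 130, 110]),
            np.tile([50.0, 52, 48], 2),
        ])
        degs = call_degs(_matrix(arr, two_stage_design), ComparisonSpec("PEC", "NEC"))
        assert degs.set_index("feature_id").loc["m0", "status"] == "up"
        assert degs.set_index("feature_id").loc["m1", "status"] == "unchanged"

    def test_precomputed_passthrough(self, two_stage_design):
        table = pd.DataFrame(
            {"feature_id": ["g1", "g2"], "log2fc": [3.61, 0.2], "status": ["up", "unchanged"]}
        )
        out = call_degs(
            _matrix(np.ones((1, 6)), two_stage_design),
            ComparisonSpec("PEC", "NEC"),
            precomputed=table,
        )
        assert list(out["status"]) == ["up", "unchanged"]

    def test_precomputed_status_derived_from_thresholds(self, two_stage_design):
        table = pd.DataFrame(
            {"feature_id": ["g1", "g2"], "log2fc": [3.61, 0.2], "fdr": [0.01, 0.01]}
        )
        out = call_degs(
            _matrix(np.ones((1, 6)), two_stage_design),
            ComparisonSpec("PEC", "NEC"),
            precomputed=table,
        )
        assert list(out["status"]) == ["up", "unchanged"]


class TestVennPartition:
    def test_center_region(self):
        regions = venn_partition({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b", "d"}})
        assert regions[("A", "B", "C")] == {"b"}

    def test_disjoint_sets(self):
        regions = venn_partition({"A": {"a"}, "B": {"b"}, "C": {"c"}})
        assert regions[("A",)] == {"a"}
        assert all(not v for k, v in regions.items() if len(k) > 1)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        a=st.sets(st.integers(0, 30)),
        b=st.sets(st.integers(0, 30)),
        c=st.sets(st.integers(0, 30)),
    )
    def test_regions_partition_the_union(self, a, b, c):
        regions = venn_partition({"A": a, "B": b, "C": c})
        union = a | b | c
        assert sum(len(v) for v in regions.values()) == len(union)
        assert set().union(*regions.values()) == union


class TestClassComposition:
    def test_fraction_report(self, toy_matrix):
        report = class_composition(["m1", "m2", "m3", "m4"], toy_matrix.annotations)
        assert report.loc[0, "feature_class"] == "Flavone"
        assert report.loc[0, "fraction"] == pytest.approx(0.5)
        assert report["fraction"].sum() == pytest.approx(1.0)
        assert "other" in set(report["feature_class"])  # m4 has no class

    def test_empty_set(self, toy_matrix):
        assert class_composition([], toy_matrix.annotations).empty


class TestHcaOrder:
    def test_identical_profiles_merge_first(self, two_stage_design):
        t = np.arange(1.0, 7.0)
        # rows 0 and 1 are exactly affine on the log2(x+1) scale
        arr = np.vstack([2.0**t - 1, 2.0 ** (2 * t) - 1, [9, 1, 7, 2, 8, 1.0]])
        order, _, link = hca_order(_matrix(arr, two_stage_design))
        # rows 0 and 1 are perfectly correlated: first merge at height ~0
        assert set(link[0, :2].astype(int)) == {0, 1}
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert order.index("m0") + 1 == order.index("m1") or order.index("m1") + 1 == order.index("m0")

    def test_merge_order_matches_bruteforce_distances(self, two_stage_design, rng):
        arr = rng.lognormal(size=(3, 6))
        _, _, link = hca_order(_matrix(arr, two_stage_design))
        logged = np.log2(arr + 1)
        d = {}
        for i in range(3):
            for j in range(i + 1, 3):
                d[(i, j)] = 1 - np.corrcoef(logged[i], logged[j])[0, 1]
        first = min(d, key=d.get)
        assert set(link[0, :2].astype(int)) == set(first)
        assert link[0, 2] == pytest.approx(d[first], abs=1e-10)

    def test_constant_rows_at_max_distance(self, two_stage_design):
        arr = np.array([[5.0] * 6, [1, 2, 3, 4, 5, 6.0], [6, 5, 4, 3, 2, 1.0]])
        _, _, link = hca_order(_matrix(arr, two_stage_design))
        # the constant row joins last, at the maximum correlation distance
        assert link[-1, 2] == pytest.approx(2.0)


class TestEndToEndRecovery:
    def test_planted_signal_recovered(self, small_omics):
        metabolome, _, truth = small_omics
        result = run_differential(metabolome, ComparisonSpec("PEC", "NEC"))
        called = result.set_index("feature_id")["status"]
        true = truth.dam_status["PEC_vs_NEC"]
        hits = (called != "unchanged") & (true != "unchanged")
        assert hits.sum() / (true != "unchanged").sum() >= 0.9
        assert (called[true != "unchanged"] == true[true != "unchanged"]).all()
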