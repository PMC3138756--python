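"""Loop-design estimation, normalization, calls and clustering."""

import numpy as np
import pandas as pd
import pytest

from isrna.expression import (DesignError, ExpressionMatrix,
                              LoopDesignExperiment, aggregate_probes,
                              build_experiment, call_distinct,
                              call_specificity, correlation_distance_matrix,
                              estimate_effects, hierarchical_cluster,
                              median_normalize, normalize_experiment,
                              relative_expression_tables)


def cycle_experiment(samples, M_rows, probes=("p1",)):
    """Loop over ``samples``; array i: Cy5 = s[i+1], Cy3 = s[i]."""
    n = len(samples)
    arrays = [(f"a{i}", samples[(i + 1) % n], samples[i]) for i in range(n)]
    M = pd.DataFrame(M_rows, index=[a[0] for a in arrays], columns=list(probes))
    return LoopDesignExperiment(tuple(samples), arrays, M)


class TestMedianNormalize:
    def test_hand_example(self):
        assert median_normalize(np.array([1.0, 2.0, 3.0])).tolist() == \
            [-1.0, 0.0, 1.0]

    def test_idempotent_when_median_zero(self):
        m = np.array([-1.0, 0.0, 1.0])
        assert median_normalize(m).tolist() == m.tolist()

    def test_constant_becomes_zero(self):
        assert median_normalize(np.array([3.0, 3.0, 3.0])).tolist() == [0, 0, 0]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            median_normalize(np.array([1.0, np.nan]))


class TestEstimateEffects:
    def test_three_cycle_hand_solution(self):
        # arrays (s2|s1), (s3|s2), (s1|s3) with planted mu = (-1, 0, 1)
        exp = cycle_experiment(["s1", "s2", "s3"], [[1.0], [1.0], [-2.0]])
        mat = estimate_effects(exp)
        assert mat.effects["s1"].iloc[0] == pytest.approx(-1, abs=1e-12)
        assert mat.effects["s2"].iloc[0] == pytest.approx(0, abs=1e-12)
        assert mat.effects["s3"].iloc[0] == pytest.approx(1, abs=1e-12)

    def test_all_zero_m_gives_zero_effects(self):
        exp = cycle_experiment(["s1", "s2", "s3"], [[0.0], [0.0], [0.0]])
        assert np.allclose(estimate_effects(exp).effects.to_numpy(), 0)

    def test_two_sample_closed_form(self):
        # single array Cy5 = s2, Cy3 = s1, M = m  =>  mu = (-m/2, +m/2)
        exp = LoopDesignExperiment(
            ("s1", "s2"), [("a0", "s2", "s1")],
            pd.DataFrame([[0.8]], index=["a0"], columns=["p1"]))
        mat = estimate_effects(exp)
        assert mat.effects.loc["p1", "s1"] == pytest.approx(-0.4)
        assert mat.effects.loc["p1", "s2"] == pytest.approx(0.4)

    def test_sum_zero_constraint(self):
        rng = np.random.default_rng(0)
        exp = cycle_experiment(list("abcde"), rng.normal(size=(5, 7)),
                               probes=[f"p{i}" for i in range(7)])
        mat = estimate_effects(exp)
        assert np.allclose(mat.effects.sum(axis=1), 0, atol=1e-12)

    def test_disconnected_design_rejected(self):
        M = pd.DataFrame([[0.0], [0.0]], index=["a0", "a1"], columns=["p1"])
        with pytest.raises(DesignError, match="disconnected"):
            LoopDesignExperiment(("s1", "s2", "s3", "s4"),
                                 [("a0", "s1", "s2"), ("a1", "s3", "s4")], M)

    def test_underdetermined_design_rejected(self):
        M = pd.DataFrame([[0.0]], index=["a0"], columns=["p1"])
        exp = LoopDesignExperiment.__new__(LoopDesignExperiment)
        exp.samples = ("s1", "s2", "s3")
        exp.arrays = [("a0", "s1", "s2")]
        exp.M = M
        with pytest.raises(DesignError):
            estimate_effects(exp)

    def test_offset_invariance_after_normalization(self):
        rng = np.random.default_rng(3)
        M = rng.normal(size=(4, 9))
        exp = cycle_experiment(list("wxyz"), M, probes=[f"p{i}" for i in range(9)])
        base = estimate_effects(normalize_experiment(exp)).effects
        M2 = M.copy()
        M2[2, :] += 5.0  # constant dye/offset shift on one array
        exp2 = cycle_experiment(list("wxyz"), M2,
                                probes=[f"p{i}" for i in range(9)])
        shifted = estimate_effects(normalize_experiment(exp2)).effects
        assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-12)


class TestBuildExperiment:
    def test_replicates_average_to_m(self):
        design = pd.DataFrame({"array_id": ["a0"], "cy5_sample": ["s2"],
                               "cy3_sample": ["s1"]})
        rows = [{"array_id": "a0", "probe_id": "p1", "replicate": r,
                 "cy5": 2.0 ** (10 + m / 2), "cy3": 2.0 ** (10 - m / 2)}
                for r, m in [(1, 0.9), (2, 1.0), (3, 1.1)]]
        exp = build_experiment(design, pd.DataFrame(rows))
        assert exp.M.loc["a0", "p1"] == pytest.approx(1.0)

    def test_non_positive_intensity_rejected(self):
        design = pd.DataFrame({"array_id": ["a0"], "cy5_sample": ["s2"],
                               "cy3_sample": ["s1"]})
        rows = pd.DataFrame([{"array_id": "a0", "probe_id": "p1",
                              "replicate": 1, "cy5": 0.0, "cy3": 4.0}])
        with pytest.raises(ValueError, match="non-positive"):
            build_experiment(design, rows)


class TestAggregateAndTables:
    def test_probe_averaging(self):
        effects = pd.DataFrame(
            [[1.0, -1.0], [3.0, -3.0]], index=["t1_p1", "t1_p2"],
            columns=["s1", "s2"])
        mat = ExpressionMatrix(effects)
        agg = aggregate_probes(mat, {"t1": ["t1_p1", "t1_p2"]})
        assert agg.effects.loc["t1"].tolist() == [2.0, -2.0]

    def test_identical_rows_zero_reference_column(self):
        effects = pd.DataFrame([[1.0, -1.0], [1.0, -1.0]],
                               index=["t1", "t2"], columns=["ref", "o"])
        t1, t2 = relative_expression_tables(ExpressionMatrix(effects), "ref")
        assert np.allclose(t1.to_numpy(), 0)
        assert np.allclose(t2["ref"].to_numpy(), 0)

    def test_single_transcript_is_its_own_mean(self):
        effects = pd.DataFrame([[0.5, -0.5]], index=["t1"], columns=["r", "o"])
        t1, _ = relative_expression_tables(ExpressionMatrix(effects), "r")
        assert t1.iloc[0, 0] == pytest.approx(0.0)

    def test_hand_computed_relative_columns(self):
        effects = pd.DataFrame([[1.0, 2.0, -3.0], [-1.0, 0.0, 1.0]],
                               index=["t1", "t2"], columns=["ref", "o", "x"])
        t1, t2 = relative_expression_tables(ExpressionMatrix(effects), "ref")
        # column-1: mu_ref - mean(mu_ref) = (1, -1) - 0
        assert t1.iloc[:, 0].tolist() == [1.0, -1.0]
        # other column: mu_o - mu_ref = (2-1, 0-(-1)) = (1, 1)
        assert t2["o"].tolist() == [1.0, 1.0]
        assert t1.iloc[:, 0].mean() == pytest.approx(0.0, abs=1e-9)

    def test_unknown_reference_rejected(self):
        effects = pd.DataFrame([[0.0, 0.0]], index=["t1"], columns=["a", "b"])
        with pytest.raises(ValueError, match="unknown reference"):
            relative_expression_tables(ExpressionMatrix(effects), "nope")


class TestCalls:
    def _mat(self, rows, samples):
        idx = [f"t{i}" for i in range(len(rows))]
        effects = pd.DataFrame(rows, index=idx, columns=samples)
        effects = effects.sub(effects.mean(axis=1), axis=0)
        return ExpressionMatrix(effects)

    def test_distinct_is_strict_greater_than(self):
        mat = self._mat([[0.0, 1.2, 0.0], [0.0, 1.0, 0.0], [0.3, 0.3, 0.3]],
                        ["a", "b", "c"])
        calls = call_distinct(mat, tau_fold=1.0)
        assert calls["distinct"].tolist() == [True, False, False]

    def test_specificity_labels(self):
        mat = self._mat([[2.0, 0.5, 0.0], [0.0, 0.0, 0.0], [-2.0, 0.0, 0.0]],
                        ["brain", "heart", "liver"])
        labels = call_specificity(mat, "brain", margin=1.0)
        assert labels.tolist() == ["predominant", "none", "depleted"]


class TestClustering:
    def test_perfectly_correlated_rows_merge_at_zero(self):
        effects = pd.DataFrame([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0],
                                [3.0, 1.0, 2.0]],
                               index=["a", "b", "c"], columns=["x", "y", "z"])
        effects = effects.sub(effects.mean(axis=1), axis=0)
        d = correlation_distance_matrix(effects)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        res = hierarchical_cluster(ExpressionMatrix(effects))
        assert res.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_distance_is_two(self):
        effects = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]],
                               index=["a", "b"], columns=["x", "y", "z"])
        effects = effects.sub(effects.mean(axis=1), axis=0)
        d = correlation_distance_matrix(effects)
        assert d[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_distance_matches_brute_force(self):
        rng = np.random.default_rng(8)
        effects = pd.DataFrame(rng.normal(size=(15, 5)),
                               index=[f"t{i}" for i in range(15)])
        effects = effects.sub(effects.mean(axis=1), axis=0)
        d = correlation_distance_matrix(effects)
        v = effects.to_numpy()
        for i in range(15):
            for j in range(15):
                r = np.corrcoef(v[i], v[j])[0, 1]
                assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_leaf_set_invariant_under_permutation(self):
        rng = np.random.default_rng(13)
        effects = pd.DataFrame(rng.normal(size=(10, 4)),
                               index=[f"t{i}" for i in range(10)])
        effects = effects.sub(effects.mean(axis=1), axis=0)
        a = hierarchical_cluster(ExpressionMatrix(effects))
        perm = effects.iloc[rng.permutation(10)]
        b = hierarchical_cluster(ExpressionMatrix(perm))
        assert sorted(a.leaf_order) == sorted(b.leaf_order)
        assert a.leaf_order == b.leaf_order  # rows are pre-sorted by id
        assert a.newick.endswith(");")

    def test_zero_variance_rows_are_named(self):
        effects = pd.DataFrame([[0.0, 0.0, 0.0], [1.0, 0.0, -1.0]],
                               index=["flat", "ok"], columns=["x", "y", "z"])
        with pytest.raises(ValueError, match="flat"):
            hierarchical_cluster(ExpressionMatrix(effects))
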