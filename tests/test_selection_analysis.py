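import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import nanoherit as nh
from nanoherit.selection_analysis import Constituent


def matrix_from(values, metrics=None) -> nh.MetricMatrix:
    values = np.asarray(values, dtype=float)
    metrics = metrics or [f"m{j}" for j in range(values.shape[1])]
    samples = [f"s{i}" for i in range(values.shape[0])]
    return nh.MetricMatrix(pd.DataFrame(values, index=samples, columns=metrics))


class TestQualityScore:
    def test_two_sample_hand_example(self):
        mat = matrix_from([[0.0, 4.0], [10.0, 8.0]])
        qd = nh.QualityDefinition("Q", (Constituent("m0", 0.5, +1),
                                        Constituent("m1", 0.5, +1)))
        scores = nh.quality_score(mat, qd)
        assert scores.tolist() == pytest.approx([0.0, 1.0])

    def test_single_constituent_preserves_ranking(self):
        rng = np.random.default_rng(0)
        mat = matrix_from(rng.normal(size=(20, 1)))
        qd = nh.QualityDefinition("Q", (Constituent("m0", 1.0, +1),))
        scores = nh.quality_score(mat, qd)
        assert (scores.rank() == mat.data["m0"].rank()).all()
        assert scores.min() == 0.0 and scores.max() == 1.0

    def test_direction_flip_reflects_scores(self):
        rng = np.random.default_rng(1)
        mat = matrix_from(rng.normal(size=(10, 1)))
        up = nh.quality_score(mat, nh.QualityDefinition(
            "Q", (Constituent("m0", 1.0, +1),)))
        down = nh.quality_score(mat, nh.QualityDefinition(
            "Q", (Constituent("m0", 1.0, -1),)))
        assert np.allclose(up + down, 1.0)

    def test_missing_constituent_errors(self):
        mat = matrix_from([[1.0], [2.0]])
        qd = nh.QualityDefinition("Q", (Constituent("ghost", 1.0, +1),))
        with pytest.raises(nh.ValidationError, match="ghost"):
            nh.quality_score(mat, qd)

    def test_constant_constituent_names_metric(self):
        mat = matrix_from([[1.0, 3.0], [1.0, 4.0]])
        qd = nh.QualityDefinition("Q", (Constituent("m0", 1.0, +1),))
        with pytest.raises(nh.ValidationError, match="m0"):
            nh.quality_score(mat, qd)

    def test_weights_normalised(self):
        qd = nh.QualityDefinition("Q", (Constituent("a", 2.0, +1),
                                        Constituent("b", 6.0, +1)))
        assert [c.weight for c in qd.constituents] == pytest.approx([0.25, 0.75])

    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           shift=st.floats(min_value=-50.0, max_value=50.0))
    def test_affine_invariance_of_scores(self, scale, shift):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(12, 2))
        qd = nh.QualityDefinition("Q", (Constituent("m0", 0.3, +1),
                                        Constituent("m1", 0.7, -1),))
        s1 = nh.quality_score(matrix_from(base), qd)
        rescaled = base.copy()
        rescaled[:, 0] = scale * rescaled[:, 0] + shift
        s2 = nh.quality_score(matrix_from(rescaled), qd)
        assert np.allclose(s1, s2, atol=1e-9)


class TestSelectionGradient:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(2)
        trait = rng.normal(size=50)
        z = (trait - trait.mean()) / trait.std(ddof=1)
        beta = nh.selection_gradient(trait, 2.0 * z)
        assert beta == pytest.approx(2.0, abs=1e-12)

    def test_constant_fitness_gives_zero(self):
        beta = nh.selection_gradient([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_three_point_hand_ols(self):
        beta = nh.selection_gradient([0.0, 1.0, 2.0], [1.0, 3.0, 5.0],
                                     standardize_trait=False)
        assert beta == pytest.approx(2.0)

    def test_zero_trait_spread_errors(self):
        with pytest.raises(nh.ValidationError, match="zero spread"):
            nh.selection_gradient([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_points_errors(self):
        with pytest.raises(nh.ValidationError, match="at least 3"):
            nh.selection_gradient([1.0, 2.0], [1.0, 2.0])

    @given(scale=st.floats(min_value=0.01, max_value=100.0),
           shift=st.floats(min_value=-10.0, max_value=10.0))
    def test_standardised_gradient_affine_invariant(self, scale, shift):
        rng = np.random.default_rng(3)
        trait = rng.normal(size=30)
        fitness = rng.uniform(size=30)
        b1 = nh.selection_gradient(trait, fitness)
        b2 = nh.selection_gradient(scale * trait + shift, fitness)
        assert b2 == pytest.approx(b1, rel=1e-9, abs=1e-12)


class TestGMatrix:
    def test_duplicated_metric_has_unit_correlation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        mat = matrix_from(np.column_stack([x, x]), metrics=["a", "a_copy"])
        G = nh.g_matrix(mat)
        assert G.values.loc["a", "a_copy"] == pytest.approx(1.0)

    def test_standardized_diagonal_is_ones(self):
        rng = np.random.default_rng(5)
        G = nh.g_matrix(matrix_from(rng.normal(size=(40, 5))))
        assert np.allclose(np.diag(G.values), 1.0)

    def test_independent_metrics_off_diagonals_small(self):
        rng = np.random.default_rng(7)
        G = nh.g_matrix(matrix_from(rng.normal(size=(5000, 4))))
        off = G.values.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_raw_covariance_mode(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(100, 3))
        G = nh.g_matrix(matrix_from(X), standardized=False)
        assert np.allclose(G.values, np.cov(X, rowvar=False), atol=1e-12)

    def test_single_sample_errors(self):
        with pytest.raises(nh.ValidationError, match="at least 2"):
            nh.g_matrix(matrix_from([[1.0, 2.0]]))


class TestPredictedResponse:
    def test_identity_g_returns_beta(self):
        G = nh.GMatrix(("x", "y"), pd.DataFrame(np.eye(2), index=["x", "y"],
                                                columns=["x", "y"]))
        dz = nh.predicted_response(G, {"x": 0.5, "y": -1.5})
        assert dz.tolist() == pytest.approx([0.5, -1.5])

    def test_hand_two_by_two(self):
        G = nh.GMatrix(("x", "y"), pd.DataFrame([[2.0, 1.0], [1.0, 3.0]],
                                                index=["x", "y"],
                                                columns=["x", "y"]))
        dz = nh.predicted_response(G, {"x": 1.0, "y": -1.0})
        assert dz.tolist() == pytest.approx([1.0, -2.0])

    def test_null_selection_gives_null_response(self):
        rng = np.random.default_rng(9)
        G = nh.g_matrix(matrix_from(rng.normal(size=(30, 3))))
        dz = nh.predicted_response(G, {m: 0.0 for m in G.labels})
        assert np.allclose(dz, 0.0)

    def test_label_mismatch_lists_unmatched(self):
        G = nh.GMatrix(("x", "y"), pd.DataFrame(np.eye(2), index=["x", "y"],
                                                columns=["x", "y"]))
        with pytest.raises(nh.ValidationError, match="z"):
            nh.predicted_response(G, {"x": 1.0, "z": 2.0})

    @given(seed=st.integers(min_value=0, max_value=500))
    def test_matches_brute_force_expansion(self, seed):
        # element-wise double loop over the expanded multivariate equation
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(25, 6))
        labels = [f"m{j}" for j in range(6)]
        G = nh.g_matrix(matrix_from(X, metrics=labels))
        beta = pd.Series(rng.normal(size=6), index=labels)
        dz = nh.predicted_response(G, beta)
        for n, metric in enumerate(labels):
            manual = sum(G.values.iloc[n, m] * beta.iloc[m] for m in range(6))
            assert dz[metric] == pytest.approx(manual, abs=1e-10)

    def test_diagonal_g_closed_form(self):
        # with no trait covariance, delta z_n = V_n * beta_n
        V = np.array([2.0, 5.0, 0.5])
        labels = ("a", "b", "c")
        G = nh.GMatrix(labels, pd.DataFrame(np.diag(V), index=labels,
                                            columns=labels))
        beta = {"a": 1.0, "b": -0.2, "c": 3.0}
        dz = nh.predicted_response(G, beta)
        for i, m in enumerate(labels):
            assert dz[m] == pytest.approx(V[i] * beta[m], abs=1e-12)


class TestCrossQuality:
    @staticmethod
    def _gradients(beta_dict):
        beta = pd.DataFrame(beta_dict)
        return nh.SelectionGradients(beta=beta, r2=beta * 0.0, n=10)

    def test_identical_definitions_have_zero_range(self):
        g = self._gradients({"Q1": {"a": 0.3, "b": -0.5},
                             "Q2": {"a": 0.3, "b": -0.5}})
        table = nh.cross_quality_table(g)
        assert (table["range"] == 0.0).all()

    def test_opposite_gradients_mean_zero_range_two(self):
        g = self._gradients({"Q1": {"a": 1.0}, "Q2": {"a": -1.0}})
        table = nh.cross_quality_table(g)
        assert table.loc["a", "mean"] == 0.0
        assert table.loc["a", "range"] == 2.0

    def test_rows_sorted_by_ascending_mean(self):
        g = self._gradients({"Q1": {"a": 1.0, "b": -1.0, "c": 0.0},
                             "Q2": {"a": 0.8, "b": -0.6, "c": 0.1}})
        table = nh.cross_quality_table(g)
        assert table.index.tolist() == ["b", "c", "a"]

    def test_single_definition_rejected(self):
        g = self._gradients({"Q1": {"a": 1.0}})
        with pytest.raises(nh.ValidationError, match="at least 2"):
            nh.cross_quality_table(g)

    def test_shared_driver_has_smaller_range_than_specific_one(self):
        # metric A is a constituent of both quality definitions, metric B of
        # only one: B's gradient must swing more across definitions
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 3))
        mat = matrix_from(X, metrics=["A", "B", "C"])
        q1 = nh.QualityDefinition("Q1", (Constituent("A", 0.5, +1),
                                         Constituent("B", 0.5, +1)))
        q2 = nh.QualityDefinition("Q2", (Constituent("A", 0.5, +1),
                                         Constituent("C", 0.5, +1)))
        grads = nh.selection_gradients(mat, [q1, q2])
        table = nh.cross_quality_table(grads)
        assert table.loc["A", "range"] < table.loc["B", "range"]
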