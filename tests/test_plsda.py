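import pickle

import numpy as np
import pytest

from pplsda.dataio import center_columns, dummy_code, sample_weights
from pplsda.plsda import (
    PLSDA,
    between_group_factor,
    dominant_direction,
    fit_plsda,
    project,
)


def brute_force_B(Xc, labels, priors):
    """Independent oracle: B = sum_g (pi_g / n) m_g m_g^T directly."""
    groups = np.unique(labels)
    n = Xc.shape[0]
    B = np.zeros((Xc.shape[1], Xc.shape[1]))
    for g, pi in zip(groups, priors):
        m = Xc[labels == g].mean(axis=0)
        B += pi / n * np.outer(m, m)
    return B


def _prep(X, labels, priors="empirical"):
    Xc, _ = center_columns(X)
    return Xc, dummy_code(labels), sample_weights(labels, priors)


class TestBetweenGroupFactor:
    def test_symmetric_toy_group_means_and_B(self, symmetric_toy):
        X, labels = symmetric_toy
        Xc, dummy, pri = _prep(X, labels, (0.5, 0.5))
        bgf = between_group_factor(Xc, dummy, pri)
        np.testing.assert_allclose(bgf.group_means, [[1, 1], [-1, -1]])
        B = bgf.factor.T @ bgf.factor
        np.testing.assert_allclose(B / B[0, 0], [[1, 1], [1, 1]])

    def test_no_between_group_signal_gives_zero_B(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        labels = np.array(["A", "A", "B", "B"])
        Xc, dummy, pri = _prep(X, labels)
        bgf = between_group_factor(Xc, dummy, pri)
        np.testing.assert_allclose(bgf.factor.T @ bgf.factor, 0, atol=1e-15)

    def test_unbalanced_empirical_matches_brute_force(self, rng):
        X = rng.normal(size=(11, 6))
        labels = np.array(["A"] * 7 + ["B"] * 4)
        Xc, dummy, pri = _prep(X, labels)
        bgf = between_group_factor(Xc, dummy, pri)
        np.testing.assert_allclose(
            bgf.factor.T @ bgf.factor,
            brute_force_B(Xc, labels, pri.priors),
            atol=1e-12,
        )


class TestDominantDirection:
    def test_symmetric_toy_direction(self, symmetric_toy):
        X, labels = symmetric_toy
        bgf = between_group_factor(*_prep(X, labels, (0.5, 0.5)))
        np.testing.assert_allclose(dominant_direction(bgf), np.ones(2) / np.sqrt(2))

    def test_collinear_with_mean_difference(self, rng):
        X = rng.normal(size=(20, 15))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        Xc, dummy, pri = _prep(X, labels)
        w = dominant_direction(between_group_factor(Xc, dummy, pri))
        diff = Xc[:10].mean(axis=0) - Xc[10:].mean(axis=0)
        cos = abs(w @ diff) / np.linalg.norm(diff)
        assert cos > 1 - 1e-10

    @pytest.mark.parametrize("seed", range(10))
    def test_reduced_eigenproblem_matches_dense_oracle(self, seed):
        """g x g route vs dense p x p eigendecomposition of B."""
        rng = np.random.default_rng(seed)
        n, p = rng.integers(8, 20), rng.integers(5, 50)
        X = rng.normal(size=(n, p))
        labels = np.array(["A"] * (n // 2) + ["B"] * (n - n // 2))
        Xc, dummy, pri = _prep(X, labels)
        w = dominant_direction(between_group_factor(Xc, dummy, pri))
        B = brute_force_B(Xc, labels, pri.priors)
        vals, vecs = np.linalg.eigh(B)
        w_ref = vecs[:, -1]
        assert abs(w @ w_ref) > 1 - 1e-8

    def test_high_dimensional_instance_matches_dense_oracle(self):
        rng = np.random.default_rng(99)
        X = rng.normal(size=(30, 2000))
        labels = np.array(["A"] * 15 + ["B"] * 15)
        Xc, dummy, pri = _prep(X, labels)
        w = dominant_direction(between_group_factor(Xc, dummy, pri))
        B = brute_force_B(Xc, labels, pri.priors)
        _, vecs = np.linalg.eigh(B)
        assert abs(w @ vecs[:, -1]) > 1 - 1e-8

    def test_zero_factor_raises(self):
        X = np.array([[1.0, 0], [-1, 0], [0, 1], [0, -1]])
        labels = np.array(["A", "A", "B", "B"])
        bgf = between_group_factor(*_prep(X, labels))
        with pytest.raises(ValueError, match="between-group"):
            dominant_direction(bgf)


class TestFitPLSDA:
    def test_toy_scores_separate_groups(self, symmetric_toy):
        X, labels = symmetric_toy
        m = PLSDA(n_components=1).fit(X, labels)
        t = m.x_scores_[:, 0]
        assert t[:2].min() > t[2:].max() or t[2:].min() > t[:2].max()

    def test_score_orthogonality_after_deflation(self, separable_dataset):
        m = PLSDA(n_components=3).fit(separable_dataset.matrix, separable_dataset.labels)
        T = m.x_scores_
        for i in range(3):
            for j in range(i + 1, 3):
                cos = abs(T[:, i] @ T[:, j]) / (
                    np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                )
                assert cos < 1e-8

    def test_unit_norm_weights(self, separable_dataset):
        m = PLSDA(n_components=3).fit(separable_dataset.matrix, separable_dataset.labels)
        np.testing.assert_allclose(
            np.linalg.norm(m.x_weights_, axis=0), 1.0, atol=1e-10
        )

    def test_internal_centering_idempotent(self, separable_dataset):
        X = separable_dataset.matrix
        y = separable_dataset.labels
        m1 = PLSDA(n_components=2).fit(X, y)
        m2 = PLSDA(n_components=2).fit(X - X.mean(axis=0), y)
        np.testing.assert_allclose(m1.x_scores_, m2.x_scores_, atol=1e-10)
        np.testing.assert_allclose(m1.x_weights_, m2.x_weights_, atol=1e-10)

    def test_too_many_components_error_names_achievable(self):
        X = np.array([[1.0, 1], [2, 2], [3, 3.000001], [4, 4]])
        labels = np.array(["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="achievable"):
            PLSDA(n_components=5).fit(np.tile(X, (1, 1)), labels)


class TestProject:
    def test_training_matrix_reproduces_training_scores(self, separable_dataset):
        m = fit_plsda(separable_dataset, n_components=3)
        T = project(m, separable_dataset.matrix)
        np.testing.assert_allclose(T, m.x_scores_, atol=1e-8)

    def test_single_training_row(self, separable_dataset):
        m = fit_plsda(separable_dataset, n_components=2)
        row = separable_dataset.matrix[[5]]
        np.testing.assert_allclose(
            project(m, row)[0], m.x_scores_[5], atol=1e-8
        )

    def test_constant_shift_absorbed_by_centering(self, symmetric_toy):
        # a global shift present at fit time is removed by the stored
        # centering, so shifted model + shifted data reproduce the original
        X, labels = symmetric_toy
        m = PLSDA(n_components=1).fit(X, labels)
        m_shift = PLSDA(n_components=1).fit(X + 3.5, labels)
        np.testing.assert_allclose(
            m_shift.transform(X + 3.5), m.transform(X), atol=1e-10
        )

    def test_dimension_mismatch_raises(self, separable_dataset):
        m = fit_plsda(separable_dataset, n_components=1)
        with pytest.raises(ValueError, match="features"):
            m.transform(np.ones((2, 7)))


def test_model_pickle_round_trip_is_bit_exact(separable_dataset):
    m = fit_plsda(separable_dataset, n_components=3)
    m2 = pickle.loads(pickle.dumps(m))
    for attr in ("x_weights_", "x_loadings_", "x_scores_", "x_mean_", "gamma_"):
        np.testing.assert_array_equal(getattr(m, attr), getattr(m2, attr))
    np.testing.assert_array_equal(
        m.transform(separable_dataset.matrix), m2.transform(separable_dataset.matrix)
    )
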