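import numpy as np
import pytest

from pplsda.dataio import center_columns, dummy_code, sample_weights
from pplsda.plsda import PLSDA
from pplsda.pplsda import (
    PoweredPLSDA,
    _fit_fixed_arrays,
    candidate_weights,
    cca_objective,
    fit_pplsda,
    optimize_gamma_cc,
)


def _prep(X, labels, priors="empirical"):
    Xc, _ = center_columns(X)
    return Xc, dummy_code(labels), sample_weights(labels, priors)


def make_two_feature_toy():
    """Feature 0: high std (2), moderate |rho|; feature 1: std 1, |rho| = 1.

    Class vector c = (+,+,-,-); feature 1 equals c exactly, feature 0 is
    scaled with a sign flip inside one class so its correlation is partial.
    """
    c = np.array([1.0, 1.0, -1.0, -1.0])
    f1 = c.copy()
    f0 = 2.0 * np.array([1.0, -1.0, -1.0, 1.0]) + c  # std > 1, |rho| < 1
    X = np.column_stack([f0, f1])
    labels = np.array(["A", "A", "B", "B"])
    return X, labels


class TestCandidateWeights:
    def test_endpoint_indicators(self):
        X, labels = make_two_feature_toy()
        Xc, dummy, pri = _prep(X, labels)
        w0 = candidate_weights(Xc, dummy, pri, 0.0).matrix[:, 0]
        assert abs(w0[0]) == 1.0 and w0[1] == 0.0  # max-std feature
        w1 = candidate_weights(Xc, dummy, pri, 1.0).matrix[:, 0]
        assert w1[0] == 0.0 and abs(w1[1]) == 1.0  # max-|rho| feature

    def test_gamma_half_collinear_with_covariance_weights(self, rng):
        X = rng.normal(size=(20, 12)) * rng.uniform(0.5, 3.0, size=12)
        labels = np.array(["A"] * 10 + ["B"] * 10)
        Xc, dummy, pri = _prep(X, labels)
        w = candidate_weights(Xc, dummy, pri, 0.5).matrix[:, 0]
        # independent oracle: plain covariance with the first dummy column
        d = dummy.D[:, 0] - dummy.D[:, 0].mean()
        cov = Xc.T @ d / len(d)
        cos = abs(w @ cov) / np.linalg.norm(cov)
        assert cos > 1 - 1e-10

    def test_zero_variance_feature_gets_zero_weight(self):
        X, labels = make_two_feature_toy()
        X = np.column_stack([X, np.full(4, 7.0)])
        Xc, dummy, pri = _prep(X, labels)
        for gamma in (0.0, 0.3, 0.5, 0.9, 1.0):
            W = candidate_weights(Xc, dummy, pri, gamma).matrix
            np.testing.assert_array_equal(W[2], 0.0)

    def test_unit_norm_columns(self, rng):
        X = rng.normal(size=(16, 8))
        labels = np.array(["A"] * 8 + ["B"] * 8)
        Xc, dummy, pri = _prep(X, labels)
        for gamma in (0.2, 0.5, 0.8):
            W = candidate_weights(Xc, dummy, pri, gamma).matrix
            np.testing.assert_allclose(np.linalg.norm(W, axis=0), 1.0, atol=1e-10)

    def test_gamma_outside_unit_interval_rejected(self):
        X, labels = make_two_feature_toy()
        Xc, dummy, pri = _prep(X, labels)
        with pytest.raises(ValueError):
            candidate_weights(Xc, dummy, pri, 1.2)


def brute_force_cca(Z, Dc, v, n_grid=2000):
    """Oracle: maximize |weighted corr(Z a, Dc b)| over unit vectors on a
    fine angular grid (both blocks are rank <= 2)."""
    best = 0.0
    angles = np.linspace(0, np.pi, n_grid)
    cb = Dc[:, 0]  # rank-1 response block
    for th in angles:
        a = np.array([np.cos(th), np.sin(th)])
        za = Z @ a
        zc = za - v @ za
        dc = cb - v @ cb
        den = np.sqrt((v @ (zc * zc)) * (v @ (dc * dc)))
        if den > 0:
            best = max(best, abs(v @ (zc * dc)) / den)
    return best


class TestCcaObjective:
    def test_perfect_correlation_gives_one(self):
        X, labels = make_two_feature_toy()
        Xc, dummy, pri = _prep(X, labels)
        obj = cca_objective(Xc, dummy, pri, 1.0)  # indicator on the exact feature
        assert obj.value == pytest.approx(1.0, abs=1e-8)

    def test_orthogonal_projection_gives_zero(self):
        # feature orthogonal to the class contrast
        X = np.array([[1.0, 0], [-1, 0], [1, 0], [-1, 0]]) + np.array(
            [[0, 1], [0, 1], [0, -1], [0, -1]]
        ) * 0
        X[:, 1] = [0.1, -0.1, 0.1, -0.1]
        labels = np.array(["A", "A", "B", "B"])
        Xc, dummy, pri = _prep(X, labels)
        obj = cca_objective(Xc, dummy, pri, 0.0)
        assert obj.value == pytest.approx(0.0, abs=1e-6)

    def test_matches_brute_force_grid_oracle(self, rng):
        X = rng.normal(size=(20, 10))
        labels = np.array(["A"] * 10 + ["B"] * 10)
        Xc, dummy, pri = _prep(X, labels)
        obj = cca_objective(Xc, dummy, pri, 0.3)
        from pplsda.pplsda import _power_weights, _weighted_stats

        kw = pri.weight_diagonal
        v = kw / kw.sum()
        rho, s, Dc, _ = _weighted_stats(Xc, dummy.D, kw)
        Z = Xc @ _power_weights(rho, s, 0.3)
        assert obj.value == pytest.approx(brute_force_cca(Z, Dc, v), abs=1e-3)

    def test_invariant_to_feature_reordering(self, rng):
        X = rng.normal(size=(16, 9))
        labels = np.array(["A"] * 8 + ["B"] * 8)
        perm = rng.permutation(9)
        Xc, dummy, pri = _prep(X, labels)
        Xp, _, _ = _prep(X[:, perm], labels)
        for gamma in (0.25, 0.6):
            v1 = cca_objective(Xc, dummy, pri, gamma).value
            v2 = cca_objective(Xp, dummy, pri, gamma).value
            assert v1 == pytest.approx(v2, abs=1e-10)

    def test_invariant_to_label_swap(self, rng):
        X = rng.normal(size=(16, 9))
        labels = np.array(["A"] * 8 + ["B"] * 8)
        swapped = np.where(labels == "A", "B", "A")
        Xc, d1, p1 = _prep(X, labels)
        _, d2, p2 = _prep(X, swapped)
        for gamma in (0.25, 0.6):
            assert cca_objective(Xc, d1, p1, gamma).value == pytest.approx(
                cca_objective(Xc, d2, p2, gamma).value, abs=1e-10
            )


class TestOptimizeGammaCc:
    def test_max_correlation_endpoint_wins(self, rng):
        # one feature equal to the class vector among equal-std noise
        n = 20
        c = np.array([1.0] * 10 + [-1.0] * 10)
        noise = rng.normal(0, 1, size=(n, 30))
        noise /= noise.std(axis=0)
        X = np.column_stack([noise[:, :15], c, noise[:, 15:]])
        labels = np.array(["A"] * 10 + ["B"] * 10)
        Xc, dummy, pri = _prep(X, labels)
        gamma, value = optimize_gamma_cc(Xc, dummy, pri)
        assert gamma == 1.0
        assert value == pytest.approx(1.0, abs=1e-8)

    def test_flat_objective_returns_half(self):
        # two identical features: every gamma gives the same single direction
        c = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        X = np.column_stack([c, c])
        labels = np.array(["A", "A", "A", "B", "B", "B"])
        Xc, dummy, pri = _prep(X, labels)
        gamma, _ = optimize_gamma_cc(Xc, dummy, pri)
        assert gamma == 0.5

    def test_within_001_of_exhaustive_grid(self, rng):
        X = rng.normal(size=(30, 50)) * rng.uniform(0.3, 3.0, size=50)
        X[:15, :4] += 0.8
        labels = np.array(["A"] * 15 + ["B"] * 15)
        Xc, dummy, pri = _prep(X, labels)
        gamma, value = optimize_gamma_cc(Xc, dummy, pri)
        grid = np.arange(0.0, 1.0001, 0.001)
        vals = [cca_objective(Xc, dummy, pri, g).value for g in grid]
        best = grid[int(np.argmax(vals))]
        assert value >= max(vals) - 1e-6
        assert abs(gamma - best) <= 0.01 or value == pytest.approx(
            max(vals), abs=1e-6
        )


class TestFitPPLSDA:
    def test_fixed_half_equals_plsda_scores(self, case3_train):
        m_pls = PLSDA(n_components=3).fit(case3_train.matrix, case3_train.labels)
        m_pow = PoweredPLSDA(n_components=3, gamma=0.5).fit(
            case3_train.matrix, case3_train.labels
        )
        assert np.abs(m_pls.x_scores_ - m_pow.x_scores_).max() < 1e-8

    def test_cc_mode_concentrates_on_informative_feature(self, rng):
        n = 30
        c = np.array([1.0] * 15 + [-1.0] * 15)
        noise = rng.normal(0, 1, size=(n, 40))
        noise /= noise.std(axis=0)
        X = np.column_stack([c + rng.normal(0, 0.01, n), noise])
        labels = np.array(["A"] * 15 + ["B"] * 15)
        m = PoweredPLSDA(n_components=1, gamma="cc").fit(X, labels)
        w = np.abs(m.x_weights_[:, 0])
        assert w[0] > 0.99

    def test_three_components_contract(self, case3_train):
        m = PoweredPLSDA(n_components=3, gamma="cc").fit(
            case3_train.matrix, case3_train.labels
        )
        assert m.gamma_.shape == (3,)
        assert np.all((m.gamma_ >= 0) & (m.gamma_ <= 1))
        T = m.x_scores_
        for i in range(3):
            for j in range(i + 1, 3):
                cos = abs(T[:, i] @ T[:, j]) / (
                    np.linalg.norm(T[:, i]) * np.linalg.norm(T[:, j])
                )
                assert cos < 1e-8

    def test_fast_path_matches_estimator(self, case3_train):
        X = case3_train.matrix
        y = case3_train.labels
        Xc, dummy, pri = _prep(X, y)
        W, P, T = _fit_fixed_arrays(Xc, dummy.D, pri.weight_diagonal, 0.7, 4)
        m = PoweredPLSDA(n_components=4, gamma=0.7).fit(X, y)
        np.testing.assert_allclose(T, m.x_scores_, atol=1e-10)

    def test_fit_pplsda_wrapper(self, separable_dataset):
        m = fit_pplsda(separable_dataset, n_components=2, gamma=0.5)
        assert m.x_scores_.shape == (separable_dataset.n_samples, 2)


def test_endpoint_consistency_near_gamma_one(rng):
    """gamma -> 1- converges to the max-|rho| indicator when it is unique."""
    X = rng.normal(size=(24, 15))
    X[:12, 3] += 3.0  # feature 3 clearly most correlated
    labels = np.array(["A"] * 12 + ["B"] * 12)
    Xc, dummy, pri = _prep(X, labels)
    w_near = candidate_weights(Xc, dummy, pri, 0.999).matrix[:, 0]
    w_ind = candidate_weights(Xc, dummy, pri, 1.0).matrix[:, 0]
    assert abs(w_near @ w_ind) > 0.99
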