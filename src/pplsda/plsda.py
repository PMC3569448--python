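"""Prior-weighted PLS discriminant analysis.

Each latent component's loading-weight vector is the dominant eigenvector
of the between-group sum-of-squares matrix B of the (deflated) data.  B has
rank at most g-1 and factors as B = A^T A with A a g x p matrix of
prior-scaled group means, so the p x p eigenproblem collapses to the g x g
problem on A A^T; the eigenvector is back-transformed to feature space.
Components are extracted NIPALS-style: score t = X w, loading
p = X^T t / (t^T t), deflation X <- X - t p^T.  New data are projected by
repeating the deflation with the stored weights and loadings, which
reproduces the rotation W (P^T W)^{-1} exactly and makes the leading-a
columns of the scores equal to an a-component fit (prefix property).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .dataio import (
    CenteringVector,
    DummyResponse,
    ExpressionDataset,
    PriorSpec,
    center_columns,
    dummy_code,
    sample_weights,
)

__all__ = [
    "BetweenGroupFactor",
    "PLSDA",
    "between_group_factor",
    "dominant_direction",
    "fit_plsda",
    "project",
]

MAX_COMPONENTS = 5


@dataclass(frozen=True)
class BetweenGroupFactor:
    """Factor A of the between-group matrix B = A^T A.

    Row g of ``factor`` is sqrt(pi_g / n) * m_g, with m_g the group mean of
    the centered data, so that A^T A equals the prior-weighted between-group
    sum-of-squares matrix sum_g (pi_g / n) m_g m_g^T.
    """

    factor: np.ndarray
    group_means: np.ndarray


def between_group_factor(
    Xc: np.ndarray, dummy: DummyResponse, priors: PriorSpec
) -> BetweenGroupFactor:
    """Group means and the g x p factor of the between-group matrix."""
    Xc = np.asarray(Xc, dtype=float)
    counts = dummy.D.sum(axis=0)
    if np.any(counts == 0):
        raise ValueError("empty group in dummy response")
    group_means = (dummy.D.T @ Xc) / counts[:, None]
    n = Xc.shape[0]
    scale = np.sqrt(priors.priors / n)
    return BetweenGroupFactor(factor=scale[:, None] * group_means, group_means=group_means)


def _fix_sign(w: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Deterministic sign: first entry with non-negligible magnitude positive."""
    nz = np.flatnonzero(np.abs(w) > tol * max(1.0, np.abs(w).max()))
    if nz.size and w[nz[0]] < 0:
        return -w
    return w


def dominant_direction(bgf: BetweenGroupFactor) -> np.ndarray:
    """Dominant eigenvector of B = A^T A via the small g x g eigenproblem.

    Eigendecomposes A A^T (g x g), back-transforms the leading eigenvector
    to feature space through A^T and normalizes.  Sign is fixed so the
    first non-negligible entry is positive.
    """
    A = bgf.factor
    small = A @ A.T
    norm = np.linalg.norm(A)
    if norm == 0 or not np.any(np.abs(small) > 0):
        raise ValueError("no between-group variation")
    vals, vecs = np.linalg.eigh(small)
    w = A.T @ vecs[:, -1]
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("no between-group variation")
    return _fix_sign(w / nrm)


def _fit_plsda_arrays(Xc, D, kw_priors, ncomp):
    """Validation-free PLS-DA fit on pre-centered arrays; returns (W, P, T).

    ``kw_priors`` is the length-g prior vector (not the sample diagonal).
    """
    n, p = Xc.shape
    scale = np.sqrt(kw_priors / n)
    W = np.empty((p, ncomp))
    P = np.empty((p, ncomp))
    T = np.empty((n, ncomp))
    counts = D.sum(axis=0)
    Xd = Xc.copy()
    for comp in range(ncomp):
        means = (D.T @ Xd) / counts[:, None]
        A = scale[:, None] * means
        small = A @ A.T
        vals, vecs = np.linalg.eigh(small)
        w = A.T @ vecs[:, -1]
        nrm = np.linalg.norm(w)
        if nrm <= 1e-14:
            raise ValueError(f"only {comp} components achievable")
        w = _fix_sign(w / nrm)
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-28:
            raise ValueError(f"only {comp} components achievable")
        pload = Xd.T @ t / tt
        Xd -= np.outer(t, pload)
        W[:, comp], P[:, comp], T[:, comp] = w, pload, t
    return W, P, T


class PLSDA(TransformerMixin, BaseEstimator):
    """PLS-DA latent-component transformer for two-group data.

    Parameters
    ----------
    n_components : int, default=2
        Number of latent components to extract (at most 5).
    priors : "empirical" or length-2 array, default="empirical"
        Group prior probabilities entering the between-group matrix.

    Attributes
    ----------
    x_weights_ : ndarray of shape (n_features, n_components)
        Unit-norm loading weights, one column per component.
    x_loadings_ : ndarray of shape (n_features, n_components)
        Loadings used for deflation and projection.
    x_scores_ : ndarray of shape (n_samples, n_components)
        Training scores (mutually orthogonal columns).
    x_mean_ : ndarray of shape (n_features,)
        Training column means (centering vector).
    gamma_ : ndarray of shape (n_components,)
        Power-parameter record; the constant 0.5 marks plain PLS-DA.
    classes_ : ndarray of shape (2,)
        Sorted group symbols.
    """

    def __init__(self, n_components: int = 2, priors="empirical"):
        self.n_components = n_components
        self.priors = priors

    def _component_weight(self, Xd, dummy, prior_spec, rank_tol):
        bgf = between_group_factor(Xd, dummy, prior_spec)
        if np.linalg.norm(bgf.factor) <= rank_tol:
            return None
        return dominant_direction(bgf)

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        ncomp = int(self.n_components)
        if not 1 <= ncomp <= MAX_COMPONENTS:
            raise ValueError(f"n_components must be in 1..{MAX_COMPONENTS}, got {ncomp}")
        dummy = dummy_code(y)
        prior_spec = sample_weights(y, self.priors)
        Xc, centering = center_columns(X)
        rank_tol = 1e-12 * max(1.0, np.linalg.norm(Xc))

        n, p = Xc.shape
        W = np.empty((p, ncomp))
        P = np.empty((p, ncomp))
        T = np.empty((n, ncomp))
        Xd = Xc.copy()
        for a in range(ncomp):
            w = self._component_weight(Xd, dummy, prior_spec, rank_tol)
            if w is None:
                raise ValueError(
                    f"requested {ncomp} components but only {a} are achievable"
                )
            t = Xd @ w
            tt = t @ t
            if tt <= rank_tol**2:
                raise ValueError(
                    f"requested {ncomp} components but only {a} are achievable"
                )
            pload = Xd.T @ t / tt
            Xd -= np.outer(t, pload)
            W[:, a], P[:, a], T[:, a] = w, pload, t
        self.classes_ = dummy.groups
        self.x_weights_ = W
        self.x_loadings_ = P
        self.x_scores_ = T
        self.x_mean_ = centering.means
        self.gamma_ = np.full(ncomp, 0.5)
        self.n_features_in_ = p
        return self

    def transform(self, X, n_components: int | None = None):
        """Project new rows onto the latent components.

        Applies the stored centering then the sequential deflation with the
        fitted weights/loadings; equivalent to the rotation W (P^T W)^{-1}.
        ``n_components`` truncates to the leading components.
        """
        check_is_fitted(self, "x_weights_")
        X = check_array(X, dtype=float, ensure_2d=True)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model was fitted with {self.n_features_in_}"
            )
        ncomp = self.x_weights_.shape[1] if n_components is None else int(n_components)
        Xd = X - self.x_mean_
        T = np.empty((X.shape[0], ncomp))
        for a in range(ncomp):
            t = Xd @ self.x_weights_[:, a]
            Xd -= np.outer(t, self.x_loadings_[:, a])
            T[:, a] = t
        return T

    @property
    def centering_(self) -> CenteringVector:
        check_is_fitted(self, "x_mean_")
        return CenteringVector(means=self.x_mean_)


def fit_plsda(dataset: ExpressionDataset, priors="empirical", n_components: int = 2) -> PLSDA:
    """Fit :class:`PLSDA` on an :class:`ExpressionDataset`."""
    return PLSDA(n_components=n_components, priors=priors).fit(dataset.matrix, dataset.labels)


def project(model, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Scores of new rows under a fitted projection model."""
    return model.transform(X, n_components=n_components)
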