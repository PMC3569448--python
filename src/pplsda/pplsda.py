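"""Powered PLS-DA: power-parameter loading weights and their optimization.

The candidate loading-weight matrix W(gamma) blends, per feature, the
correlation with the dummy response and the feature standard deviation:

    w_jk(gamma)  ∝  sign(rho_jk) * |rho_jk|^(gamma/(1-gamma)) * s_k^((1-gamma)/gamma)

so gamma = 0.5 recovers the classic covariance weights of PLS, gamma -> 0
degenerates to an indicator of the largest-standard-deviation feature and
gamma -> 1 to an indicator of the feature most correlated with the group
response.  Correlations and standard deviations are computed under the
prior-induced sample weighting K (diagonal pi_g / (n_g n)); with empirical
priors and balanced groups this is plain Pearson correlation.

For each component the loading-weight vector is w = W(gamma) a with a the
leading canonical-correlation combiner between Z(gamma) = X W(gamma) and
the dummy block.  gamma itself is either fixed or chosen per component by
maximizing that canonical correlation over (0, 1) with the two endpoint
indicator rules checked separately (the gamma_cc criterion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_X_y

from .dataio import (
    DummyResponse,
    ExpressionDataset,
    PriorSpec,
    center_columns,
    dummy_code,
    sample_weights,
)
from .plsda import MAX_COMPONENTS, PLSDA, _fix_sign

__all__ = [
    "CandidateWeights",
    "CcaObjective",
    "PoweredPLSDA",
    "candidate_weights",
    "cca_objective",
    "optimize_gamma_cc",
    "fit_pplsda",
]

_TINY = 1e-300


@dataclass(frozen=True)
class CandidateWeights:
    """Candidate loading-weight matrix W(gamma), one unit-norm column per
    dummy-response column."""

    gamma: float
    matrix: np.ndarray


@dataclass(frozen=True)
class CcaObjective:
    """Leading canonical correlation between Z(gamma) = X W(gamma) and the
    dummy block, with the Z-side combiner a."""

    gamma: float
    value: float
    combiner: np.ndarray


def _weighted_stats(Xc: np.ndarray, D: np.ndarray, kw: np.ndarray):
    """Weighted feature std and per-dummy-column correlations.

    ``kw`` is the K diagonal (any positive scale); internally normalized to
    sum 1.  Returns (rho: g x p, s: length-p, Dc: weighted-centered dummy,
    sd: length-g dummy stds).
    """
    v = kw / kw.sum()
    mu = v @ Xc
    Xw = Xc - mu
    s = np.sqrt(v @ (Xw * Xw))
    Dc = D - v @ D
    sd = np.sqrt((v[:, None] * Dc * Dc).sum(axis=0))
    cov = (v[:, None] * Dc).T @ Xw  # g x p
    denom = np.outer(sd, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    # a feature whose variance was (numerically) removed by deflation has a
    # correlation made of rounding noise; treat it as uninformative
    if s.size:
        rho[:, s <= 1e-9 * s.max()] = 0.0
    return rho, s, Dc, sd


def _power_weights(rho: np.ndarray, s: np.ndarray, gamma: float) -> np.ndarray:
    """W(gamma) columns from precomputed correlations/stds (p x g)."""
    g, p = rho.shape
    W = np.zeros((p, g))
    if gamma == 0.0 or gamma == 1.0:
        for j in range(g):
            if gamma == 0.0:
                usable = s > 0
                crit = np.where(usable, s, -np.inf)
            else:
                usable = (s > 0) & (np.abs(rho[j]) > 0)
                crit = np.where(usable, np.abs(rho[j]), -np.inf)
            if not usable.any():
                continue
            k = int(np.argmax(crit))  # ties -> lowest index
            sign = np.sign(rho[j, k]) or 1.0
            W[k, j] = sign
        return W
    e_rho = gamma / (1.0 - gamma)
    e_s = (1.0 - gamma) / gamma
    log_s = np.log(np.maximum(s, _TINY))
    for j in range(g):
        absr = np.abs(rho[j])
        mask = (s > 0) & (absr > 0)
        if not mask.any():
            continue
        logw = e_rho * np.log(np.maximum(absr[mask], _TINY)) + e_s * log_s[mask]
        logw -= logw.max()  # overflow guard; scale is normalized away
        col = np.zeros(p)
        col[mask] = np.sign(rho[j, mask]) * np.exp(logw)
        nrm = np.linalg.norm(col)
        if nrm > 0:
            W[:, j] = col / nrm
    return W


def _cca(Z: np.ndarray, Dc: np.ndarray, kw: np.ndarray):
    """Leading weighted canonical correlation of Z vs the centered dummy
    block; returns (value in [0,1], combiner a on the Z side)."""
    v = kw / kw.sum()
    Zc = Z - v @ Z
    Szz = Zc.T @ (v[:, None] * Zc)
    Sdd = Dc.T @ (v[:, None] * Dc)
    Szd = Zc.T @ (v[:, None] * Dc)
    g = Szz.shape[0]
    if not np.any(np.abs(Szz) > 0):
        warnings.warn("projection Z is identically zero; objective set to 0")
        return 0.0, np.zeros(g)
    rz = 1e-10 * np.trace(Szz)
    rd = 1e-10 * np.trace(Sdd)
    Szz = Szz + rz * np.eye(g)
    Sdd = Sdd + rd * np.eye(Sdd.shape[0])
    Lz = np.linalg.cholesky(Szz)
    Ld = np.linalg.cholesky(Sdd)
    C = np.linalg.solve(Lz, Szd)
    C = np.linalg.solve(Ld, C.T).T
    U, sv, _ = np.linalg.svd(C)
    value = float(np.clip(sv[0], 0.0, 1.0))
    a = np.linalg.solve(Lz.T, U[:, 0])
    nrm = np.linalg.norm(a)
    return value, a / nrm if nrm > 0 else a


def candidate_weights(
    Xc: np.ndarray, dummy: DummyResponse, priors: PriorSpec, gamma: float
) -> CandidateWeights:
    """Candidate loading-weight matrix W(gamma) for centered data."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    rho, s, _, _ = _weighted_stats(np.asarray(Xc, float), dummy.D, priors.weight_diagonal)
    return CandidateWeights(gamma=float(gamma), matrix=_power_weights(rho, s, gamma))


def cca_objective(
    Xc: np.ndarray, dummy: DummyResponse, priors: PriorSpec, gamma: float
) -> CcaObjective:
    """Canonical-correlation value of the candidate weights at ``gamma``."""
    Xc = np.asarray(Xc, float)
    kw = priors.weight_diagonal
    rho, s, Dc, _ = _weighted_stats(Xc, dummy.D, kw)
    W = _power_weights(rho, s, gamma)
    value, a = _cca(Xc @ W, Dc, kw)
    return CcaObjective(gamma=float(gamma), value=value, combiner=a)


def _optimize_gamma(Xc, D, kw, xatol: float = 1e-4):
    """argmax over gamma in [0,1] of the canonical-correlation objective.

    Interior maximum by bounded scalar minimization; the indicator rules at
    gamma = 0 and 1 are evaluated separately.  Ties go to the smaller
    gamma; a flat objective returns 0.5 with a flag.  The search itself
    uses the exact two-class correlation form (the centered dummy block has
    rank 1), avoiding the ridge of the general cca computation; the
    combiner is recovered at the selected gamma.
    """
    v = kw / kw.sum()
    rho, s, dc, sd = _stats2(Xc, D, v)
    gamma, value, flat = _optimize_gamma2(Xc, dc, sd, rho, s, v, xatol)
    Dc = D - v @ D
    # second dummy column carries the mirrored correlations
    W = _power_weights(np.vstack([rho, -rho]), s, gamma)
    _, a = _cca(Xc @ W, Dc, kw)
    return gamma, value, a, flat


def optimize_gamma_cc(
    Xc: np.ndarray, dummy: DummyResponse, priors: PriorSpec
) -> tuple[float, float]:
    """The gamma_cc criterion: gamma maximizing the canonical correlation."""
    gamma, value, _, _ = _optimize_gamma(
        np.asarray(Xc, float), dummy.D, priors.weight_diagonal
    )
    return gamma, value


def _stats2(Xd, D, v):
    """Two-class weighted stats without temporaries the size of X.

    ``v`` is the normalized weight vector.  Returns (rho, s, dc, sd) for
    the first dummy column only: with two groups the centered dummy block
    has rank 1 (second column is the negative of the first), so the full
    g-column machinery reduces to this single response.
    """
    dc = D[:, 0] - v @ D[:, 0]
    sd = np.sqrt(v @ (dc * dc))
    mu = v @ Xd
    s2 = np.einsum("i,ij,ij->j", v, Xd, Xd) - mu * mu
    s = np.sqrt(np.maximum(s2, 0.0))
    cov = (v * dc) @ Xd  # weighted cov; v @ dc == 0 kills the mean term
    smax = s.max() if s.size else 0.0
    usable = s > 1e-9 * smax
    rho = np.zeros_like(s)
    if sd > 0:
        np.divide(cov, s * sd, out=rho, where=usable)
    return rho, s, dc, sd


def _direction(rho, s, gamma):
    """Single-column candidate direction u(gamma), unit norm (or zero)."""
    p = rho.shape[0]
    u = np.zeros(p)
    if gamma == 0.0:
        if not np.any(s > 0):
            return u
        k = int(np.argmax(s))
        u[k] = np.sign(rho[k]) or 1.0
        return u
    absr = np.abs(rho)
    if gamma == 1.0:
        if not np.any(absr > 0):
            return u
        k = int(np.argmax(absr))
        u[k] = np.sign(rho[k])
        return u
    mask = absr > 0  # rho is already zeroed for dead features
    if not mask.any():
        return u
    e_rho = gamma / (1.0 - gamma)
    e_s = (1.0 - gamma) / gamma
    logw = e_rho * np.log(absr[mask]) + e_s * np.log(np.maximum(s[mask], _TINY))
    logw -= logw.max()
    u[mask] = np.sign(rho[mask]) * np.exp(logw)
    nrm = np.linalg.norm(u)
    if nrm > 0:
        u /= nrm
    return u


def _corr_value(Xd, u, dc, sd, v):
    """|weighted corr(X u, centered dummy)| — the two-class cca objective."""
    z = Xd @ u
    zc = z - v @ z
    den = np.sqrt(v @ (zc * zc)) * sd
    if den <= 0:
        return 0.0
    return min(1.0, abs((v * zc) @ dc) / den)


def _optimize_gamma2(Xd, dc, sd, rho, s, v, xatol: float = 1e-4):
    """Two-class gamma_cc search; returns (gamma, value, flat_flag)."""

    def value_at(gamma):
        return _corr_value(Xd, _direction(rho, s, gamma), dc, sd, v)

    eps = 1e-6
    res = minimize_scalar(
        lambda g: -value_at(g),
        bounds=(eps, 1.0 - eps),
        method="bounded",
        options={"xatol": xatol},
    )
    candidates = [(0.0, value_at(0.0)), (1.0, value_at(1.0)),
                  (float(res.x), min(1.0, -float(res.fun)))]
    values = [c[1] for c in candidates]
    if max(values) - min(values) < 1e-10:
        probe = [value_at(g) for g in (0.25, 0.5, 0.75)]
        if max(values + probe) - min(values + probe) < 1e-10:
            return 0.5, value_at(0.5), True
    # ties at float precision go to the exact endpoint solutions (an interior
    # gamma tying with an endpoint has collapsed onto its indicator), then to
    # the smaller gamma
    best_value = max(values)
    for gamma, value in candidates:
        if value >= best_value - 1e-12:
            return gamma, value, False


def _extract_component(Xd, u, W, P, T, comp):
    """Score/loading/deflation step shared by the fast fits."""
    nrm = np.linalg.norm(u)
    if nrm <= 1e-14:
        raise ValueError(f"only {comp} components achievable")
    w = _fix_sign(u / nrm)
    t = Xd @ w
    tt = t @ t
    if tt <= 1e-28 * max(1.0, float(np.abs(Xd).max()) ** 2):
        raise ValueError(f"only {comp} components achievable")
    pload = Xd.T @ t / tt
    Xd -= np.outer(t, pload)
    W[:, comp], P[:, comp], T[:, comp] = w, pload, t


def _fit_fixed_arrays(Xc, D, kw, gamma, ncomp):
    """Validation-free two-class fixed-gamma fit; returns (W, P, T)."""
    n, p = Xc.shape
    v = kw / kw.sum()
    W = np.empty((p, ncomp))
    P = np.empty((p, ncomp))
    T = np.empty((n, ncomp))
    Xd = Xc.copy()
    for comp in range(ncomp):
        rho, s, _, _ = _stats2(Xd, D, v)
        u = _direction(rho, s, gamma)
        _extract_component(Xd, u, W, P, T, comp)
    return W, P, T


def _fit_cc_arrays(Xc, D, kw, ncomp):
    """Validation-free per-component gamma_cc fit; returns (W, P, T, gammas)."""
    n, p = Xc.shape
    v = kw / kw.sum()
    W = np.empty((p, ncomp))
    P = np.empty((p, ncomp))
    T = np.empty((n, ncomp))
    gammas = np.empty(ncomp)
    Xd = Xc.copy()
    for comp in range(ncomp):
        rho, s, dc, sd = _stats2(Xd, D, v)
        gamma, _, _ = _optimize_gamma2(Xd, dc, sd, rho, s, v)
        u = _direction(rho, s, gamma)
        _extract_component(Xd, u, W, P, T, comp)
        gammas[comp] = gamma
    return W, P, T, gammas


def _project_arrays(X, mean, W, P):
    """Sequential-deflation projection of new rows (all fitted components)."""
    Xd = X - mean
    ncomp = W.shape[1]
    T = np.empty((X.shape[0], ncomp))
    for a in range(ncomp):
        t = Xd @ W[:, a]
        Xd -= np.outer(t, P[:, a])
        T[:, a] = t
    return T


class PoweredPLSDA(TransformerMixin, BaseEstimator):
    """Powered PLS-DA latent-component transformer.

    Parameters
    ----------
    n_components : int, default=2
        Number of components (at most 5).
    gamma : float in [0, 1] or "cc", default="cc"
        Fixed power parameter, or ``"cc"`` to optimize it per component by
        canonical-correlation maximization on the (deflated) training data.
    priors : "empirical" or length-2 array, default="empirical"

    Attributes
    ----------
    x_weights_, x_loadings_, x_scores_, x_mean_, classes_ :
        As in :class:`~pplsda.plsda.PLSDA`.
    gamma_ : ndarray of shape (n_components,)
        The power parameter used for each component.
    cca_ : ndarray of shape (n_components,)
        Canonical-correlation objective value per component.
    """

    def __init__(self, n_components: int = 2, gamma="cc", priors="empirical"):
        self.n_components = n_components
        self.gamma = gamma
        self.priors = priors

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        ncomp = int(self.n_components)
        if not 1 <= ncomp <= MAX_COMPONENTS:
            raise ValueError(f"n_components must be in 1..{MAX_COMPONENTS}, got {ncomp}")
        per_component = isinstance(self.gamma, str)
        if per_component and self.gamma != "cc":
            raise ValueError(f"gamma must be a float in [0,1] or 'cc', got {self.gamma!r}")
        if not per_component and not 0.0 <= float(self.gamma) <= 1.0:
            raise ValueError(f"gamma must lie in [0, 1], got {self.gamma}")
        dummy = dummy_code(y)
        kw = sample_weights(y, self.priors).weight_diagonal
        Xc, centering = center_columns(X)
        rank_tol = 1e-12 * max(1.0, np.linalg.norm(Xc))

        n, p = Xc.shape
        W = np.empty((p, ncomp))
        P = np.empty((p, ncomp))
        T = np.empty((n, ncomp))
        gammas = np.empty(ncomp)
        ccas = np.empty(ncomp)
        Xd = Xc.copy()
        for comp in range(ncomp):
            if per_component:
                gamma, value, a, _ = _optimize_gamma(Xd, dummy.D, kw)
                rho, s, Dc, _sd = _weighted_stats(Xd, dummy.D, kw)
                Wg = _power_weights(rho, s, gamma)
            else:
                gamma = float(self.gamma)
                rho, s, Dc, _sd = _weighted_stats(Xd, dummy.D, kw)
                Wg = _power_weights(rho, s, gamma)
                value, a = _cca(Xd @ Wg, Dc, kw)
            w = Wg @ a
            nrm = np.linalg.norm(w)
            if nrm <= rank_tol:
                raise ValueError(
                    f"requested {ncomp} components but only {comp} are achievable"
                )
            w = _fix_sign(w / nrm)
            t = Xd @ w
            tt = t @ t
            if tt <= rank_tol**2:
                raise ValueError(
                    f"requested {ncomp} components but only {comp} are achievable"
                )
            pload = Xd.T @ t / tt
            Xd -= np.outer(t, pload)
            W[:, comp], P[:, comp], T[:, comp] = w, pload, t
            gammas[comp], ccas[comp] = gamma, value
        self.classes_ = dummy.groups
        self.x_weights_ = W
        self.x_loadings_ = P
        self.x_scores_ = T
        self.x_mean_ = centering.means
        self.gamma_ = gammas
        self.cca_ = ccas
        self.n_features_in_ = p
        return self

    # projection is identical to plain PLS-DA
    transform = PLSDA.transform
    centering_ = PLSDA.centering_


def fit_pplsda(
    dataset: ExpressionDataset,
    priors="empirical",
    n_components: int = 2,
    gamma="cc",
) -> PoweredPLSDA:
    """Fit :class:`PoweredPLSDA` on an :class:`ExpressionDataset`."""
    return PoweredPLSDA(n_components=n_components, gamma=gamma, priors=priors).fit(
        dataset.matrix, dataset.labels
    )
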