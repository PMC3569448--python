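"""Hyperparameter selection by inner Monte-Carlo cross-validation.

Two selectors are provided:

* :func:`select_gamma_pe` — the prediction-optimized power parameter: one
  gamma grid, q random stratified 0.7/0.3 splits of the outer training
  set, a fixed-gamma powered PLS-DA fit with the maximal component count
  per (gamma, split), LDA prediction error evaluated on the leading
  1..max components, averaged over splits, and the joint
  (gamma, n_components) minimizer returned (ties: smaller PE, then fewer
  components, then smaller gamma).

* :func:`select_ncomp_cv` — the 10-repeat Monte-Carlo CV of the component
  count used by PLS-DA, gamma_cc, and fixed-gamma models.

Evaluating the 1..A leading components of one A-component fit equals
refitting at each count because deflation makes the model a prefix chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset, dummy_code, sample_weights
from .plsda import MAX_COMPONENTS, _fit_plsda_arrays
from .pplsda import _fit_cc_arrays, _fit_fixed_arrays, _project_arrays

__all__ = [
    "GammaGrid",
    "InnerCvResult",
    "mc_split",
    "select_gamma_pe",
    "select_ncomp_cv",
]


@dataclass(frozen=True)
class GammaGrid:
    """Equidistant gamma values 0, step, ..., 1 (both endpoints included)."""

    step: float = 0.1
    values: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        step = float(self.step)
        if not 0.0 < step <= 0.5:
            raise ValueError(f"grid step must lie in (0, 0.5], got {step}")
        n = int(round(1.0 / step))
        if abs(n * step - 1.0) > 1e-9:
            raise ValueError(f"grid step {step} does not divide [0, 1] evenly")
        object.__setattr__(self, "values", np.linspace(0.0, 1.0, n + 1))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class InnerCvResult:
    """Inner-CV prediction errors and the selected (gamma, n_components).

    ``pe_tensor`` has shape (n_grid, q, max_components); ``mean_pe`` is its
    average over the split axis.
    """

    grid: GammaGrid
    pe_tensor: np.ndarray
    mean_pe: np.ndarray
    gamma_star: float
    ncomp_star: int
    achieved_mean_pe: float


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def mc_split(n_samples: int, labels, fraction: float = 0.7, rng=None):
    """One stratified Monte-Carlo train/test split.

    Per group, round(fraction * n_g) samples (round half away from zero)
    go to the training part, the rest to the test part.  Both groups must
    end up represented on both sides.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    if len(labels) != n_samples:
        raise ValueError("labels length does not match n_samples")
    groups = np.unique(labels)
    train, test = [], []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        k = _round_half_up(fraction * len(idx))
        if k < 1 or k >= len(idx):
            raise ValueError(
                f"group {g!r} with {len(idx)} samples cannot be stratified "
                f"at fraction {fraction}"
            )
        perm = rng.permutation(idx)
        train.append(perm[:k])
        test.append(perm[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def _draw_split(n, labels, fraction, rng, max_failures: int = 100):
    """mc_split with the redraw-on-degeneracy contract."""
    failures = 0
    while True:
        try:
            return mc_split(n, labels, fraction, rng)
        except ValueError:
            failures += 1
            if failures >= max_failures:
                raise


def _lda_pe_prefix(Ttr, mask_tr, Tte, mask_te, max_comp):
    """LDA prediction error on the leading 1..max_comp score columns.

    Two-class pooled-covariance LDA with empirical priors; exact ties go
    to the first class in sorted order.
    """
    n = Ttr.shape[0]
    n0 = int(mask_tr.sum())
    n1 = n - n0
    pe = np.empty(max_comp)
    logpri = np.log(n0 / n), np.log(n1 / n)
    for a in range(1, max_comp + 1):
        T0 = Ttr[mask_tr, :a]
        T1 = Ttr[~mask_tr, :a]
        m0 = T0.mean(axis=0)
        m1 = T1.mean(axis=0)
        R0 = T0 - m0
        R1 = T1 - m1
        S = (R0.T @ R0 + R1.T @ R1) / (n - 2)
        S = (S + S.T) / 2.0
        if np.linalg.cond(S) > 1e12:
            S = S + (1e-8 * np.trace(S) / a) * np.eye(a)
        Sinv = np.linalg.inv(S)
        Tq = Tte[:, :a]
        d0 = Tq @ (Sinv @ m0) - 0.5 * m0 @ Sinv @ m0 + logpri[0]
        d1 = Tq @ (Sinv @ m1) - 0.5 * m1 @ Sinv @ m1 + logpri[1]
        pred0 = d0 >= d1  # tie -> first class
        pe[a - 1] = np.mean(pred0 != mask_te)
    return pe


def _prepare_arrays(dataset: ExpressionDataset):
    dummy = dummy_code(dataset.labels)
    X = np.ascontiguousarray(dataset.matrix, dtype=float)
    mask = dataset.labels == dummy.groups[0]
    return X, dummy, mask


def _inner_pe_for_fit(fit, X, D, labels, mask, tr, te, priors, max_comp):
    """Fit on the training part of a split and return the 1..max_comp PE."""
    Xtr = X[tr]
    mean = Xtr.mean(axis=0)
    Xc = Xtr - mean
    Dtr = D[tr]
    kw = sample_weights(labels[tr], priors).weight_diagonal
    pri = sample_weights(labels[tr], priors).priors
    if fit == "plsda":
        W, P, T = _fit_plsda_arrays(Xc, Dtr, pri, max_comp)
    elif fit == "cc":
        W, P, T, _ = _fit_cc_arrays(Xc, Dtr, kw, max_comp)
    else:  # fixed gamma
        W, P, T = _fit_fixed_arrays(Xc, Dtr, kw, float(fit), max_comp)
    Tte = _project_arrays(X[te], mean, W, P)
    return _lda_pe_prefix(T, mask[tr], Tte, mask[te], max_comp)


def select_gamma_pe(
    outer_train: ExpressionDataset,
    grid: GammaGrid | float = 0.1,
    q: int = 50,
    max_components: int = MAX_COMPONENTS,
    rng=None,
    priors="empirical",
    fraction: float = 0.7,
) -> InnerCvResult:
    """Joint (gamma, n_components) selection minimizing inner LDA PE."""
    if not isinstance(grid, GammaGrid):
        grid = GammaGrid(step=grid)
    if q < 1:
        raise ValueError("q must be at least 1")
    rng = np.random.default_rng(rng)
    X, dummy, mask = _prepare_arrays(outer_train)
    n = outer_train.n_samples
    splits = [_draw_split(n, outer_train.labels, fraction, rng) for _ in range(q)]

    pe = np.empty((len(grid), q, max_components))
    for si, (tr, te) in enumerate(splits):
        Xtr = X[tr]
        mean = Xtr.mean(axis=0)
        Xc = Xtr - mean
        Dtr = dummy.D[tr]
        kw = sample_weights(outer_train.labels[tr], priors).weight_diagonal
        Xte = X[te]
        for gi, gamma in enumerate(grid.values):
            W, P, T = _fit_fixed_arrays(Xc, Dtr, kw, float(gamma), max_components)
            Tte = _project_arrays(Xte, mean, W, P)
            pe[gi, si] = _lda_pe_prefix(T, mask[tr], Tte, mask[te], max_components)

    mean_pe = pe.mean(axis=1)
    # joint minimizer; ties -> fewer components, then smaller gamma
    best = None
    for gi in range(len(grid)):
        for a in range(max_components):
            key = (mean_pe[gi, a], a, gi)
            if best is None or key < best:
                best = key
    return InnerCvResult(
        grid=grid,
        pe_tensor=pe,
        mean_pe=mean_pe,
        gamma_star=float(grid.values[best[2]]),
        ncomp_star=best[1] + 1,
        achieved_mean_pe=float(best[0]),
    )


def select_ncomp_cv(
    outer_train: ExpressionDataset,
    fit_method="plsda",
    repeats: int = 10,
    max_components: int = MAX_COMPONENTS,
    rng=None,
    priors="empirical",
    fraction: float = 0.7,
) -> int:
    """Component count minimizing mean PE over ``repeats`` random splits.

    ``fit_method`` is ``"plsda"``, ``"cc"`` (per-component gamma_cc), or a
    float (fixed gamma).  Ties go to the fewest components.
    """
    rng = np.random.default_rng(rng)
    X, dummy, mask = _prepare_arrays(outer_train)
    n = outer_train.n_samples
    pe = np.empty((repeats, max_components))
    for r in range(repeats):
        tr, te = _draw_split(n, outer_train.labels, fraction, rng)
        pe[r] = _inner_pe_for_fit(
            fit_method, X, dummy.D, outer_train.labels, mask, tr, te, priors,
            max_components,
        )
    return int(np.argmin(pe.mean(axis=0))) + 1
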