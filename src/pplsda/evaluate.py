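"""Outer evaluation harness: balanced splits, repeated runs, CIs.

Each repeat draws one balanced outer training set (round(0.7 * smallest
group size) samples per group, majority group down-sampled) shared by all
methods, runs every method's own hyperparameter selection on that
training set only, and records the outer-test prediction error.  Across
repeats the harness reports per-method mean PE with Student-t 95%
confidence intervals and calls a method pair significantly different when
their intervals are disjoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import prediction_error, svm_linear, t_lda
from .dataio import ExpressionDataset
from .pipeline import PPLSDAClassifier
from .plsda import MAX_COMPONENTS
from .selection import _round_half_up

logger = logging.getLogger(__name__)

__all__ = [
    "OuterSplit",
    "OuterEvaluation",
    "outer_split",
    "run_experiment",
    "confidence_interval",
    "compare_methods",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = (
    "pplsda-pe",
    "pplsda-cc",
    "pplsda-fixed:0.5",
    "plsda",
    "t-lda",
    "svm",
)


@dataclass(frozen=True)
class OuterSplit:
    """Balanced outer training indices and the remaining test indices."""

    train: np.ndarray
    test: np.ndarray


def outer_split(
    dataset: ExpressionDataset, rng=None, fraction: float = 0.7
) -> OuterSplit:
    """Balanced outer split with majority down-sampling.

    Per group, round(fraction * n_min) samples (n_min the smallest group
    size) are drawn without replacement into the training set; everything
    else is the test set.
    """
    rng = np.random.default_rng(rng)
    labels = dataset.labels
    groups, counts = np.unique(labels, return_counts=True)
    n_min = counts.min()
    if n_min < 3:
        raise ValueError("smallest group must have at least 3 samples")
    k = _round_half_up(fraction * n_min)
    if k < 2 or k >= n_min:
        raise ValueError(f"fraction {fraction} leaves no test samples in a group")
    train = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        train.append(rng.permutation(idx)[:k])
    train = np.sort(np.concatenate(train))
    test = np.setdiff1d(np.arange(len(labels)), train)
    return OuterSplit(train=train, test=test)


@dataclass
class OuterEvaluation:
    """Per-repeat PEs and selection records for each method."""

    methods: list
    repeats: int
    pe: dict
    selected_gamma: dict
    selected_ncomp: dict
    failures: list = field(default_factory=list)
    level: float = 0.95

    @property
    def mean_pe(self) -> dict:
        return {m: float(np.nanmean(v)) for m, v in self.pe.items()}

    @property
    def ci(self) -> dict:
        return {
            m: confidence_interval(v[~np.isnan(v)], self.level)
            for m, v in self.pe.items()
        }

    def summary(self) -> pd.DataFrame:
        rows = []
        for m in self.methods:
            lo, hi = self.ci[m]
            v = self.pe[m]
            rows.append(
                {
                    "method": m,
                    "mean_pe": float(np.nanmean(v)),
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "mean_ncomp": float(np.nanmean(self.selected_ncomp[m])),
                    "n_repeats": int(np.sum(~np.isnan(v))),
                }
            )
        return pd.DataFrame(rows)

    def results(self) -> pd.DataFrame:
        rows = []
        for m in self.methods:
            for r in range(self.repeats):
                rows.append(
                    {
                        "method": m,
                        "repeat": r,
                        "pe": self.pe[m][r],
                        "gamma": self.selected_gamma[m][r],
                        "ncomp": self.selected_ncomp[m][r],
                    }
                )
        return pd.DataFrame(rows)


def confidence_interval(pe_vector, level: float = 0.95):
    """Student-t interval mean +- t_{1-a/2, R-1} sd / sqrt(R), clipped to [0,1]."""
    v = np.asarray(pe_vector, dtype=float)
    R = len(v)
    if R < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    m = v.mean()
    half = stats.t.ppf(0.5 + level / 2, R - 1) * v.std(ddof=1) / np.sqrt(R)
    return float(max(0.0, m - half)), float(min(1.0, m + half))


def compare_methods(evaluation: OuterEvaluation) -> pd.DataFrame:
    """Symmetric boolean matrix: True where the two CIs are disjoint."""
    methods = evaluation.methods
    ci = evaluation.ci
    out = pd.DataFrame(False, index=methods, columns=methods)
    for i, a in enumerate(methods):
        for b in methods[i + 1 :]:
            lo_a, hi_a = ci[a]
            lo_b, hi_b = ci[b]
            disjoint = hi_a < lo_b or hi_b < lo_a
            out.loc[a, b] = out.loc[b, a] = bool(disjoint)
    return out


def _parse_method(name: str):
    if name in ("plsda", "t-lda", "svm", "pplsda-pe", "pplsda-cc"):
        return name, None
    if name.startswith("pplsda-fixed"):
        gamma = 0.5
        if ":" in name:
            gamma = float(name.split(":", 1)[1])
        return "pplsda-fixed", gamma
    raise ValueError(f"unknown method {name!r}")


def _run_method(name, train, test, *, q, grid_step, max_components, priors, rng):
    kind, gamma = _parse_method(name)
    if kind == "t-lda":
        return t_lda(train, test), np.nan, np.nan
    if kind == "svm":
        return svm_linear(train, test, random_state=rng.integers(2**31)), np.nan, np.nan
    method = {"plsda": "plsda", "pplsda-cc": "cc", "pplsda-fixed": "fixed",
              "pplsda-pe": "pe"}[kind]
    clf = PPLSDAClassifier(
        method=method,
        gamma=gamma if gamma is not None else 0.5,
        q=q,
        grid_step=grid_step,
        max_components=max_components,
        priors=priors,
        random_state=rng,
    )
    clf.fit(train.matrix, train.labels)
    pe = prediction_error(clf.predict(test.matrix), test.labels)
    if method == "pe":
        sel_gamma = clf.inner_cv_.gamma_star
    elif method == "fixed":
        sel_gamma = gamma
    elif method == "cc":
        sel_gamma = float(clf.gamma_[0])  # first-component gamma_cc
    else:
        sel_gamma = np.nan
    return pe, sel_gamma, clf.n_components_


def run_experiment(
    data,
    methods=DEFAULT_METHODS,
    repeats: int = 100,
    q: int = 50,
    grid_step: float = 0.1,
    max_components: int = MAX_COMPONENTS,
    base_seed: int = 0,
    priors="empirical",
    outer_fraction: float = 0.7,
) -> OuterEvaluation:
    """Run the full outer evaluation.

    Parameters
    ----------
    data : ExpressionDataset or callable(rng) -> ExpressionDataset
        A fixed dataset (re-split every repeat) or a generator called with
        a fresh random stream per repeat (simulation studies).
    methods : sequence of method names
        Any of ``plsda``, ``pplsda-cc``, ``pplsda-fixed[:gamma]``,
        ``pplsda-pe``, ``t-lda``, ``svm``.
    repeats, q, grid_step, max_components : experiment parameters.
    base_seed : int
        Root seed; every repeat and method derives an independent
        substream from it (outer splits are shared across methods).
    outer_fraction : float
        Outer training proportion of the smallest group (0.7 by default;
        0.5 reproduces a half/half split).
    """
    methods = list(methods)
    if not methods:
        raise ValueError("methods must be nonempty")
    root = np.random.SeedSequence(base_seed)
    repeat_seeds = root.spawn(repeats)
    pe = {m: np.full(repeats, np.nan) for m in methods}
    sel_gamma = {m: np.full(repeats, np.nan) for m in methods}
    sel_ncomp = {m: np.full(repeats, np.nan) for m in methods}
    failures = []
    for r in range(repeats):
        streams = repeat_seeds[r].spawn(3)
        data_rng = np.random.default_rng(streams[0])
        split_rng = np.random.default_rng(streams[1])
        dataset = data(data_rng) if callable(data) else data
        split = outer_split(dataset, split_rng, fraction=outer_fraction)
        train = dataset.subset(split.train)
        test = dataset.subset(split.test)
        for m in methods:
            # every method re-creates the same inner stream, so equivalent
            # methods see identical inner splits (the shared-segments rule)
            rng = np.random.default_rng(streams[2])
            try:
                pe[m][r], sel_gamma[m][r], sel_ncomp[m][r] = _run_method(
                    m, train, test,
                    q=q, grid_step=grid_step, max_components=max_components,
                    priors=priors, rng=rng,
                )
            except Exception as exc:  # record, never silently drop
                failures.append((r, m, str(exc)))
                logger.warning("repeat %d method %s failed: %s", r, m, exc)
    return OuterEvaluation(
        methods=methods,
        repeats=repeats,
        pe=pe,
        selected_gamma=sel_gamma,
        selected_ncomp=sel_ncomp,
        failures=failures,
    )
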