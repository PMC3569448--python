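"""Terminal classifiers: LDA on latent scores, plus the two baselines.

The PLS variants all hand their component scores to a linear discriminant
analysis with pooled within-class covariance and (by default) empirical
class priors.  Two reference classifiers operate directly in feature
space: t-LDA (LDA on the ten features with smallest two-sample t-test
p-values, computed on the training set only) and a linear support-vector
machine with its cost tuned by 10-fold cross-validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .dataio import ExpressionDataset

__all__ = [
    "LdaModel",
    "fit_lda",
    "predict_lda",
    "prediction_error",
    "t_lda",
    "svm_linear",
    "DEFAULT_COST_GRID",
]

# logarithmic cost grid for the linear SVM wrapper
DEFAULT_COST_GRID = tuple(10.0 ** np.arange(-3, 4))


@dataclass(frozen=True)
class LdaModel:
    """Gaussian LDA with pooled covariance on a small score space."""

    class_means: np.ndarray
    pooled_covariance: np.ndarray
    priors: np.ndarray
    class_order: np.ndarray
    _inv_cov: np.ndarray


def fit_lda(scores: np.ndarray, labels, priors=None) -> LdaModel:
    """Fit LDA on component scores.

    ``priors=None`` uses the empirical class proportions of the training
    labels.  A small ridge (1e-8 * mean eigenvalue scale) stabilizes the
    pooled covariance when it is ill-conditioned.
    """
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    if T.shape[0] == 1 and np.asarray(labels).shape[0] != 1:
        T = T.T
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training samples")
    n, a = T.shape
    means = np.vstack([T[labels == g].mean(axis=0) for g in groups])
    S = np.zeros((a, a))
    for gi, g in enumerate(groups):
        R = T[labels == g] - means[gi]
        S += R.T @ R
    S /= n - len(groups)
    S = (S + S.T) / 2.0
    if np.linalg.cond(S) > 1e12:
        S = S + (1e-8 * np.trace(S) / a) * np.eye(a)
    if priors is None:
        pri = counts / n
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()
    try:
        inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular pooled covariance") from exc
    return LdaModel(
        class_means=means,
        pooled_covariance=S,
        priors=pri,
        class_order=groups,
        _inv_cov=inv,
    )


def predict_lda(model: LdaModel, scores: np.ndarray) -> np.ndarray:
    """Class labels by the linear discriminant rule (log-prior included).

    Exact ties go deterministically to the earlier class in sorted order.
    """
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    a = model.class_means.shape[1]
    if T.shape[1] != a:
        raise ValueError(f"scores have {T.shape[1]} columns, model expects {a}")
    M = model.class_means
    proj = T @ model._inv_cov @ M.T
    offset = 0.5 * np.einsum("ij,jk,ik->i", M, model._inv_cov, M)
    disc = proj - offset + np.log(np.maximum(model.priors, 1e-300))
    return model.class_order[np.argmax(disc, axis=1)]


def prediction_error(predicted, truth) -> float:
    """Proportion of wrongly classified samples."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape or predicted.size == 0:
        raise ValueError("predicted and truth must be equal-length, non-empty")
    return float(np.mean(predicted != truth))


def t_lda(
    train: ExpressionDataset,
    test: ExpressionDataset,
    n_features: int = 10,
    equal_var: bool = False,
) -> float:
    """LDA on the features with the smallest two-sample t-test p-values.

    The t-test (Welch by default) and the ranking use the training set
    only; the returned value is the test-set prediction error.
    """
    groups = train.groups
    Xa = train.matrix[train.labels == groups[0]]
    Xb = train.matrix[train.labels == groups[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(Xa, Xb, axis=0, equal_var=equal_var)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    k = min(n_features, train.n_features)
    if k < n_features:
        warnings.warn(
            f"only {k} features available; t-LDA requested {n_features}"
        )
    selected = np.sort(np.argsort(pvals, kind="stable")[:k])
    model = fit_lda(train.matrix[:, selected], train.labels)
    pred = predict_lda(model, test.matrix[:, selected])
    return prediction_error(pred, test.labels)


def svm_linear(
    train: ExpressionDataset,
    test: ExpressionDataset,
    cost_grid=DEFAULT_COST_GRID,
    folds: int = 10,
    random_state=None,
) -> float:
    """Linear-kernel SVM baseline; cost tuned by stratified k-fold CV.

    A thin wrapper over an established maximum-margin implementation; the
    returned value is the test-set prediction error.
    """
    seed = None if random_state is None else int(np.asarray(random_state).item()) % (2**31)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="linear"),
        {"C": list(cost_grid)},
        cv=cv,
        scoring="accuracy",
        n_jobs=None,
    )
    search.fit(train.matrix, train.labels)
    pred = search.best_estimator_.predict(test.matrix)
    return prediction_error(pred, test.labels)
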