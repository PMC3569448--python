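"""Dataset container, dummy coding, centering and prior-based sample weights.

Expression data are handled as a samples x features matrix of log-scale
intensities together with a two-level group label per sample.  All
downstream fitting works on the validated :class:`ExpressionDataset`
container; file input goes through :func:`load_dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "DummyResponse",
    "PriorSpec",
    "CenteringVector",
    "load_dataset",
    "dummy_code",
    "center_columns",
    "sample_weights",
]


@dataclass(frozen=True)
class ExpressionDataset:
    """A validated two-group expression matrix.

    Attributes
    ----------
    matrix : ndarray of shape (n_samples, n_features)
        Log-scale expression values, finite.
    labels : ndarray of shape (n_samples,)
        Group label per sample; exactly two distinct levels.
    sample_ids : ndarray of shape (n_samples,)
        Unique sample identifiers.
    feature_ids : ndarray of shape (n_features,)
        Unique feature identifiers.
    """

    matrix: np.ndarray
    labels: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        labels = np.asarray(self.labels)
        sample_ids = np.asarray(self.sample_ids)
        feature_ids = np.asarray(self.feature_ids)
        object.__setattr__(self, "matrix", X)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)
        if X.ndim != 2:
            raise ValueError("matrix must be two-dimensional")
        n, p = X.shape
        if not np.all(np.isfinite(X)):
            raise ValueError("matrix contains missing or non-finite entries")
        if n < 4 or p < 2:
            raise ValueError(f"need at least 4 samples and 2 features, got {n}x{p}")
        if labels.shape != (n,):
            raise ValueError("labels length does not match number of samples")
        if sample_ids.shape != (n,) or len(set(map(str, sample_ids))) != n:
            raise ValueError("sample_ids must be unique and match the sample count")
        if feature_ids.shape != (p,) or len(set(map(str, feature_ids))) != p:
            raise ValueError("feature_ids must be unique and match the feature count")
        groups, counts = np.unique(labels, return_counts=True)
        if len(groups) != 2:
            raise ValueError(f"exactly 2 group levels required, got {len(groups)}")
        if counts.min() < 2:
            raise ValueError("each group needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def groups(self) -> np.ndarray:
        """The two group symbols in sorted (lexicographic) order."""
        return np.unique(self.labels)

    @property
    def group_sizes(self) -> np.ndarray:
        groups, counts = np.unique(self.labels, return_counts=True)
        return counts

    def subset(self, indices: np.ndarray) -> "ExpressionDataset":
        """Row subset as a new dataset (used by the split machinery)."""
        idx = np.asarray(indices)
        return ExpressionDataset(
            matrix=self.matrix[idx],
            labels=self.labels[idx],
            sample_ids=self.sample_ids[idx],
            feature_ids=self.feature_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        """Samples x features table with a trailing ``group`` column."""
        df = pd.DataFrame(self.matrix, index=self.sample_ids, columns=self.feature_ids)
        df.insert(len(df.columns), "group", self.labels)
        df.index.name = "sample"
        return df

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep)


@dataclass(frozen=True)
class DummyResponse:
    """0/1 group-membership coding D (n x 2) plus the signed class vector.

    Group symbols are sorted lexicographically; the first group maps to
    column 0 of ``D`` and to +1 in ``signed``.
    """

    D: np.ndarray
    signed: np.ndarray
    groups: np.ndarray


@dataclass(frozen=True)
class PriorSpec:
    """Group priors and the induced per-sample weight diagonal.

    The weight for sample *i* in group *g* is ``priors[g] / (n_g * n)`` —
    the diagonal of the weighting matrix K that carries prior information
    into the loading-weight construction.
    """

    priors: np.ndarray
    weight_diagonal: np.ndarray
    groups: np.ndarray


@dataclass(frozen=True)
class CenteringVector:
    """Column means of a training matrix; subtract to center, add to undo."""

    means: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) - self.means

    def invert(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) + self.means


def dummy_code(labels: Sequence) -> DummyResponse:
    """Dummy-code a two-level label vector.

    Returns D with one 1 per row (rows sum to 1, column sums are the group
    sizes) and the signed vector with +1 for the lexicographically first
    group and -1 for the second.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 group levels required, got {len(groups)}")
    D = (labels[:, None] == groups[None, :]).astype(float)
    signed = np.where(labels == groups[0], 1.0, -1.0)
    return DummyResponse(D=D, signed=signed, groups=groups)


def center_columns(X: np.ndarray) -> tuple[np.ndarray, CenteringVector]:
    """Center columns to mean zero; returns the centered matrix and the means."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    means = X.mean(axis=0)
    return X - means, CenteringVector(means=means)


def sample_weights(labels: Sequence, priors="empirical") -> PriorSpec:
    """Per-sample weights pi_g / (n_g * n) from group priors.

    ``priors`` is either ``"empirical"`` (group proportions) or a length-2
    sequence of nonnegative reals, normalized to sum 1, in sorted group
    order.  With empirical priors the diagonal is the constant 1/n**2.
    """
    labels = np.asarray(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) != 2:
        raise ValueError(f"exactly 2 group levels required, got {len(groups)}")
    n = len(labels)
    if isinstance(priors, str):
        if priors != "empirical":
            raise ValueError(f"unknown priors spec {priors!r}")
        pri = counts / n
    else:
        pri = np.asarray(priors, dtype=float)
        if pri.shape != (2,):
            raise ValueError("priors must have length 2")
        if np.any(pri < 0):
            raise ValueError("priors must be nonnegative")
        total = pri.sum()
        if total <= 0:
            raise ValueError("priors must not all be zero")
        pri = pri / total
    group_index = np.searchsorted(groups, labels)
    weight_diagonal = pri[group_index] / (counts[group_index] * n)
    return PriorSpec(priors=pri, weight_diagonal=weight_diagonal, groups=groups)


def load_dataset(
    path: str | Path,
    label_source: str | Path = "group",
    samples_in_rows: bool = True,
    sep: str | None = None,
) -> ExpressionDataset:
    """Read a delimited expression table into an :class:`ExpressionDataset`.

    Parameters
    ----------
    path : str or Path
        Delimited text file (tab or comma; auto-detected) with a header row
        and sample identifiers in the first column.
    label_source : str or Path
        Either the name of a label column inside the table, or the path to
        a two-column ``sample<TAB>label`` file.
    samples_in_rows : bool
        If False the table is features x samples and gets transposed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c", index_col=0)

    if not samples_in_rows:
        df = df.T
    labels = None
    if isinstance(label_source, (str,)) and label_source in df.columns:
        labels = df[label_source].astype(str).to_numpy()
        df = df.drop(columns=[label_source])
    if labels is None:
        label_path = Path(label_source)
        if not label_path.exists():
            raise ValueError(
                f"label source {label_source!r} is neither a column of {path.name} "
                "nor an existing file"
            )
        lab = pd.read_csv(label_path, sep=None, engine="python", index_col=0)
        try:
            labels = lab.iloc[:, 0].loc[df.index].astype(str).to_numpy()
        except KeyError as exc:
            raise ValueError(f"label file is missing samples present in the matrix: {exc}")

    # locate non-numeric cells before coercion so the error names them
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df.isna() | df.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing cell at sample {df.index[i]!r}, "
            f"feature {df.columns[j]!r}"
        )
    return ExpressionDataset(
        matrix=numeric.to_numpy(dtype=float),
        labels=np.asarray(labels),
        sample_ids=df.index.to_numpy(dtype=str),
        feature_ids=df.columns.to_numpy(dtype=str),
    )
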