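"""Two-class expression simulator and covariance-structure diagnostics.

Data are drawn as independent normal log-intensities: every feature has
variance sigma_b^2 + sigma_t^2 (biological plus technical) in both
classes; a small informative block of differentially expressed genes
(DEGs) additionally shifts the mean of class 1 by a per-gene effect
delta_j.  Five standard cases vary the technical variance and the effect
specification:

====  ==========  ============
case  sigma_t^2   delta
====  ==========  ============
1     0           U[0.1, 0.5]
2     sigma_b^2/4 U[0.1, 0.5]
3     sigma_b^2   U[0.1, 0.5]
4     sigma_b^2   0.2 (fixed)
5     sigma_b^2   0.5 (fixed)
====  ==========  ============

with sigma_b^2 = 0.04, 60 samples per class, 1000 genes, 10 DEGs.

The diagnostics quantify how hard a dataset is for latent-component
classifiers: the condition indexes kappa_k = sqrt(lambda_1/lambda_k) of
the feature covariance measure collinearity, and the absolute covariances
between principal-component scores and the signed class vector locate the
discriminative directions in the eigenvalue spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dataio import ExpressionDataset, dummy_code

__all__ = [
    "SimulationDesign",
    "CovarianceDiagnostics",
    "simulate_case",
    "condition_indexes",
    "pc_class_covariance",
]


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated two-class case."""

    n_per_class: int = 60
    n_features: int = 1000
    n_deg: int = 10
    sigma_b2: float = 0.04
    sigma_t2: float = 0.04
    delta_spec: tuple | float = (0.1, 0.5)  # uniform interval or fixed value
    baseline_mean: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0 or self.sigma_t2 < 0:
            raise ValueError("variances must be nonnegative")
        if not 0 <= self.n_deg <= self.n_features:
            raise ValueError("n_deg must lie in [0, n_features]")
        if self.n_per_class < 2:
            raise ValueError("need at least 2 samples per class")

    @classmethod
    def case(cls, case_id: int) -> "SimulationDesign":
        """The five standard cases (sigma_b^2 = 0.04 throughout)."""
        sb2 = 0.04
        table = {
            1: dict(sigma_t2=0.0, delta_spec=(0.1, 0.5)),
            2: dict(sigma_t2=sb2 / 4, delta_spec=(0.1, 0.5)),
            3: dict(sigma_t2=sb2, delta_spec=(0.1, 0.5)),
            4: dict(sigma_t2=sb2, delta_spec=0.2),
            5: dict(sigma_t2=sb2, delta_spec=0.5),
        }
        if case_id not in table:
            raise ValueError(f"case must be 1..5, got {case_id}")
        return cls(sigma_b2=sb2, **table[case_id])

    def draw_deltas(self, rng) -> np.ndarray:
        if isinstance(self.delta_spec, (int, float)):
            return np.full(self.n_deg, float(self.delta_spec))
        lo, hi = self.delta_spec
        return rng.uniform(lo, hi, size=self.n_deg)


@dataclass(frozen=True)
class CovarianceDiagnostics:
    """Condition indexes and scaled PC/class covariances of a dataset."""

    condition_indexes: np.ndarray
    scaled_eigenvalues: np.ndarray
    class_covariances: np.ndarray


def simulate_case(design: SimulationDesign, rng=None) -> ExpressionDataset:
    """One simulated dataset; the DEG block occupies the first features.

    Null features are N(mu0, sigma_b^2 + sigma_t^2) identically in both
    classes; DEG j gets mean mu0 + delta_j in class 1 and mu0 in class 2,
    with delta drawn once per dataset.
    """
    rng = np.random.default_rng(rng)
    n1 = n2 = design.n_per_class
    p = design.n_features
    sd = float(np.sqrt(design.sigma_b2 + design.sigma_t2))
    X = rng.normal(design.baseline_mean, sd, size=(n1 + n2, p))
    deltas = design.draw_deltas(rng)
    X[:n1, : design.n_deg] += deltas
    labels = np.array(["class1"] * n1 + ["class2"] * n2)
    return ExpressionDataset(
        matrix=X,
        labels=labels,
        sample_ids=np.array([f"s{i+1:03d}" for i in range(n1 + n2)]),
        feature_ids=np.array([f"g{j+1:04d}" for j in range(p)]),
    )


def _cov_eigenvalues(X: np.ndarray) -> np.ndarray:
    """Nonzero-part eigenvalues of the feature covariance, descending.

    Uses the n x n Gram matrix when p > n, which shares the nonzero
    spectrum with the p x p covariance.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    if p > n:
        M = Xc @ Xc.T
    else:
        M = Xc.T @ Xc
    vals = np.linalg.eigvalsh(M)[::-1] / (n - 1)
    return vals


def condition_indexes(X: np.ndarray, k: int = 5) -> np.ndarray:
    """First k condition indexes sqrt(lambda_1/lambda_k); kappa_1 == 1."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k} condition indexes")
    vals = _cov_eigenvalues(X)[:k]
    floor = vals[0] * 1e-12  # rank decided relative to the leading eigenvalue
    out = np.empty(k)
    for i, lam in enumerate(vals):
        if lam <= floor:
            warnings.warn(f"eigenvalue {i + 1} is not positive; condition index is inf")
            out[i] = np.inf
        else:
            out[i] = np.sqrt(vals[0] / lam)
    return out


def pc_class_covariance(X: np.ndarray, labels, k: int = 50) -> CovarianceDiagnostics:
    """Scaled eigenvalues and |cov(PC score, class vector)| series.

    Principal-component scores come from the SVD of the centered matrix;
    covariances use denominator n-1 and the signed class vector (+1 for
    the first sorted group).  Both series are scaled to their maxima; the
    condition indexes of the first five eigenvalues are included.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n <= 2:
        raise ValueError("need more than 2 samples")
    c = dummy_code(labels).signed
    Xc = X - X.mean(axis=0)
    U, sv, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(sv > sv[0] * 1e-12)) if sv.size else 0
    if k > rank:
        warnings.warn(f"requested {k} components but rank is {rank}; truncating")
        k = rank
    eig = sv[:k] ** 2 / (n - 1)
    Z = U[:, :k] * sv[:k]
    cc = c - c.mean()
    covs = np.abs(Z.T @ cc) / (n - 1)  # Z columns are centered already
    kappa = condition_indexes(X, k=min(5, rank))
    return CovarianceDiagnostics(
        condition_indexes=kappa,
        scaled_eigenvalues=eig / eig[0],
        class_covariances=covs / covs.max() if covs.max() > 0 else covs,
    )
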