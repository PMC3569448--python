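"""End-to-end classifier: latent projection + LDA with built-in selection.

:class:`PPLSDAClassifier` is the estimator a user normally touches.  It
projects with PLS-DA or powered PLS-DA, classifies the scores with LDA,
and — when ``n_components`` is left unset — selects its hyperparameters on
the training data exactly the way the evaluation harness does: the
``"pe"`` method selects gamma and the component count jointly by nested
Monte-Carlo cross-validation; the other methods select the component
count by 10-repeat Monte-Carlo cross-validation.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .classify import fit_lda, predict_lda
from .dataio import ExpressionDataset
from .plsda import MAX_COMPONENTS, PLSDA
from .pplsda import PoweredPLSDA
from .selection import GammaGrid, select_gamma_pe, select_ncomp_cv

__all__ = ["PPLSDAClassifier"]


class PPLSDAClassifier(ClassifierMixin, BaseEstimator):
    """Two-group classifier on (powered) PLS-DA components.

    Parameters
    ----------
    method : {"plsda", "cc", "fixed", "pe"}, default="pe"
        Projection / selection strategy: plain PLS-DA, per-component
        canonical-correlation gamma, fixed gamma, or the
        prediction-optimized joint (gamma, n_components) selection.
    gamma : float, default=0.5
        The power parameter for ``method="fixed"``; ignored otherwise.
    n_components : int or None, default=None
        Fixed component count; None selects it by cross-validation
        (jointly with gamma for ``method="pe"``).
    max_components : int, default=5
        Selection cap on the component count.
    q : int, default=50
        Inner Monte-Carlo splits for ``method="pe"``.
    grid_step : float, default=0.1
        Gamma grid step for ``method="pe"``.
    cv_repeats : int, default=10
        Monte-Carlo splits for the component-count CV of the other methods.
    inner_fraction : float, default=0.7
        Training proportion of each inner split.
    priors : "empirical" or length-2 array, default="empirical"
        Group priors for the projection weighting and the LDA.
    random_state : int, Generator or None
        Seeds the inner cross-validation splits.

    Attributes
    ----------
    projection_ : fitted :class:`PLSDA` or :class:`PoweredPLSDA`
    lda_ : fitted :class:`~pplsda.classify.LdaModel`
    gamma_ : ndarray, per-component power parameters used
    n_components_ : int, component count used
    inner_cv_ : :class:`~pplsda.selection.InnerCvResult` (``method="pe"`` only)
    classes_ : ndarray of the two group symbols, sorted
    """

    def __init__(
        self,
        method: str = "pe",
        gamma: float = 0.5,
        n_components: int | None = None,
        *,
        max_components: int = MAX_COMPONENTS,
        q: int = 50,
        grid_step: float = 0.1,
        cv_repeats: int = 10,
        inner_fraction: float = 0.7,
        priors="empirical",
        random_state=None,
    ):
        self.method = method
        self.gamma = gamma
        self.n_components = n_components
        self.max_components = max_components
        self.q = q
        self.grid_step = grid_step
        self.cv_repeats = cv_repeats
        self.inner_fraction = inner_fraction
        self.priors = priors
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_min_samples=4)
        if self.method not in ("plsda", "cc", "fixed", "pe"):
            raise ValueError(f"unknown method {self.method!r}")
        rng = np.random.default_rng(self.random_state)
        dataset = ExpressionDataset(
            matrix=X,
            labels=np.asarray(y),
            sample_ids=np.array([f"i{i}" for i in range(X.shape[0])]),
            feature_ids=np.array([f"f{j}" for j in range(X.shape[1])]),
        )
        gamma_fit = None
        self.inner_cv_ = None
        if self.n_components is not None:
            ncomp = int(self.n_components)
            if self.method == "pe":
                raise ValueError(
                    "method='pe' selects n_components itself; leave it unset"
                )
        elif self.method == "pe":
            inner = select_gamma_pe(
                dataset,
                grid=GammaGrid(step=self.grid_step),
                q=self.q,
                max_components=self.max_components,
                rng=rng,
                priors=self.priors,
                fraction=self.inner_fraction,
            )
            self.inner_cv_ = inner
            ncomp = inner.ncomp_star
            gamma_fit = inner.gamma_star
        else:
            fit_method = {"plsda": "plsda", "cc": "cc", "fixed": float(self.gamma)}[
                self.method
            ]
            ncomp = select_ncomp_cv(
                dataset,
                fit_method=fit_method,
                repeats=self.cv_repeats,
                max_components=self.max_components,
                rng=rng,
                priors=self.priors,
                fraction=self.inner_fraction,
            )

        if self.method == "plsda":
            proj = PLSDA(n_components=ncomp, priors=self.priors)
        elif self.method == "cc":
            proj = PoweredPLSDA(n_components=ncomp, gamma="cc", priors=self.priors)
        else:
            if gamma_fit is None:
                gamma_fit = float(self.gamma)
            proj = PoweredPLSDA(n_components=ncomp, gamma=gamma_fit, priors=self.priors)
        proj.fit(X, y)
        lda_priors = None if isinstance(self.priors, str) else self.priors
        self.projection_ = proj
        self.lda_ = fit_lda(proj.x_scores_, y, priors=lda_priors)
        self.gamma_ = proj.gamma_
        self.n_components_ = ncomp
        self.classes_ = proj.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def decision_scores(self, X):
        """Latent-component scores of new rows."""
        check_is_fitted(self, "projection_")
        return self.projection_.transform(X)

    def predict(self, X):
        check_is_fitted(self, "lda_")
        X = check_array(X, dtype=float)
        return predict_lda(self.lda_, self.projection_.transform(X))
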