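"""Binary logistic regression by iteratively reweighted least squares.

Self-contained maximum-likelihood engine behind coding selection, weight
derivation and the case-control association models: Newton/IRLS with a
deviance-based stopping rule, observed-information standard errors, AIC, and
Wald odds-ratio confidence intervals.  Separation and rank deficiency are
surfaced as errors rather than silently returning huge or arbitrary
coefficients — with cells as sparse as this study's top score category, an
unstable fit should fail loudly.

``LogisticIRLS`` is a scikit-learn style estimator (usable in pipelines);
``fit_logistic`` is the functional wrapper taking a ready-made design matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit
from sklearn.base import BaseEstimator

from .errors import (
    ConvergenceError,
    DegenerateInputError,
    RankDeficiencyError,
    SeparationError,
)


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit (coefficients on the log-odds scale)."""

    coefficients: np.ndarray  # intercept first, matching the design's column order
    standard_errors: np.ndarray
    log_likelihood: float
    aic: float
    n: int
    n_iter: int
    converged: bool


@dataclass(frozen=True)
class ORwithCI:
    """Odds ratio with Wald 95% (or other level) bounds and two-sided p."""

    or_value: float
    ci_low: float
    ci_high: float
    p_value: float


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tol: float,
    max_iter: int,
    separation_threshold: float,
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Newton-Raphson on the Bernoulli log-likelihood with frequency weights.

    Returns (beta, covariance, log_likelihood, n_iter, converged).
    """
    n, p = X.shape
    beta = np.zeros(p)
    # the separation guard watches slope coefficients only: a constant
    # (intercept) column legitimately grows large with uncentered covariates
    # such as age, while a diverging slope is the signature of separation
    slope_cols = np.ptp(X, axis=0) > 0
    deviance = np.inf
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        # clip keeps the log finite; fitted probs this extreme mean separation anyway
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        ll = float(w @ (y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
        wls = w * mu * (1 - mu)
        info = (X * wls[:, None]).T @ X
        grad = X.T @ (w * (y - mu))
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "information matrix became singular during iteration "
                "(fitted probabilities degenerate)"
            ) from None
        beta = beta + step
        if slope_cols.any() and np.max(np.abs(beta[slope_cols])) > separation_threshold:
            raise SeparationError(
                "coefficient magnitude exceeded "
                f"{separation_threshold} during iteration; the data are "
                "completely or quasi-completely separated and the MLE does not exist"
            )
        new_deviance = -2.0 * ll
        if abs(deviance - new_deviance) < tol:
            # converged: recompute ll/info at the final beta
            mu = expit(X @ beta)
            mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
            ll = float(w @ (y * np.log(mu_c) + (1 - y) * np.log(1 - mu_c)))
            wls = w * mu * (1 - mu)
            info = (X * wls[:, None]).T @ X
            cov = np.linalg.inv(info)
            return beta, cov, ll, it, True
        deviance = new_deviance
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    separation_threshold: float = 15.0,
) -> LogisticFit:
    """Fit a binary logistic model to a design matrix that already includes
    its intercept column.

    ``weights`` are optional frequency weights (grouped data); the effective
    sample size is their sum.  Convergence is declared when the deviance
    changes by less than ``tol`` (default 1e-8) within ``max_iter`` (default
    100) iterations.  Standard errors come from the inverse observed
    information at the MLE.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2:
        raise ValueError("design must be a 2-D matrix")
    if y.shape != (X.shape[0],):
        raise ValueError("outcome length must match design rows")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    keep = w > 0
    X, y, w = X[keep], y[keep], w[keep]
    n_eff = float(w.sum())
    if X.shape[0] < X.shape[1]:
        raise DegenerateInputError("fewer rows than coefficients")
    classes = np.unique(y)
    if len(classes) < 2:
        raise DegenerateInputError("outcome contains a single class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise RankDeficiencyError(
            "design matrix is rank deficient (collinear or duplicated columns); "
            "coefficients are not identifiable"
        )
    beta, cov, ll, n_iter, converged = _irls(
        X, y, w, tol, max_iter, separation_threshold
    )
    se = np.sqrt(np.diag(cov))
    k = X.shape[1]
    return LogisticFit(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        n=int(round(n_eff)),
        n_iter=n_iter,
        converged=converged,
    )


def model_aic(fit: LogisticFit) -> float:
    """Akaike information criterion 2k - 2*log-likelihood of a converged fit."""
    if not fit.converged:
        raise ConvergenceError("AIC requested for a non-converged fit")
    return fit.aic


def wald_or_ci(coefficient: float, se: float, level: float = 0.95) -> ORwithCI:
    """Odds ratio exp(coef) with log-symmetric Wald interval at ``level``."""
    if se <= 0:
        raise ValueError("standard error must be positive")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    or_value = float(np.exp(coefficient))
    p = float(2.0 * sps.norm.sf(abs(coefficient) / se))
    return ORwithCI(
        or_value=or_value,
        ci_low=float(np.exp(coefficient - z * se)),
        ci_high=float(np.exp(coefficient + z * se)),
        p_value=p,
    )


class LogisticIRLS(BaseEstimator):
    """Scikit-learn style binary logistic regression via IRLS.

    Unpenalized maximum likelihood (unlike ``sklearn.linear_model.
    LogisticRegression`` there is no regularization), with Wald inference.

    Parameters
    ----------
    fit_intercept : prepend an intercept column (default True).
    tol : deviance-change stopping tolerance.
    max_iter : Newton iteration cap.
    separation_threshold : coefficient magnitude treated as evidence of
        separation; exceeding it raises ``SeparationError``.

    Attributes (after ``fit``)
    --------------------------
    coef_, intercept_ : slopes and intercept on the log-odds scale.
    params_, bse_ : intercept-first coefficient and standard-error vectors.
    llf_, aic_, n_iter_, converged_ : fit diagnostics.
    """

    def __init__(
        self,
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_iter: int = 100,
        separation_threshold: float = 15.0,
    ):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter
        self.separation_threshold = separation_threshold

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        design = np.column_stack([np.ones(len(X)), X]) if self.fit_intercept else X
        res = fit_logistic(
            design,
            np.asarray(y, dtype=float),
            weights=sample_weight,
            tol=self.tol,
            max_iter=self.max_iter,
            separation_threshold=self.separation_threshold,
        )
        self.params_ = res.coefficients
        self.bse_ = res.standard_errors
        if self.fit_intercept:
            self.intercept_ = float(res.coefficients[0])
            self.coef_ = res.coefficients[1:].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = res.coefficients.copy()
        self.llf_ = res.log_likelihood
        self.aic_ = res.aic
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.n_features_in_ = X.shape[1]
        self.result_ = res
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)

    def odds_ratios(self, level: float = 0.95) -> list[ORwithCI]:
        """Wald OR/CI for each non-intercept coefficient."""
        start = 1 if self.fit_intercept else 0
        return [
            wald_or_ci(float(b), float(s), level)
            for b, s in zip(self.params_[start:], self.bse_[start:])
        ]
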