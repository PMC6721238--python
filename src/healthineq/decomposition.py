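"""Probit-based decomposition of the Erreygers-corrected concentration index.

A weighted probit model ``P(y=1|x) = Phi(x'b)`` links binary utilization to
its determinants.  With partial effects evaluated at the sample means,
``b_k^m = b_k * phi(xbar'b)``, the corrected index decomposes as

    E = 4 * sum_k (b_k^m xbar_k) CI_k  +  GCI_eps,

where ``CI_k`` is the (standard) concentration index of regressor ``x_k``
over the income ranks and ``GCI_eps`` the generalized concentration index of
the error term.  Each covariate's contribution ``4 * elasticity * CI_k``
combines its effect on utilization with its income gradient; the residual is
the part of measured inequality the systematic part does not explain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import log_ndtr, ndtr
from sklearn.base import BaseEstimator

from .concentration import (
    RankedSample,
    erreygers_index,
    generalized_ci,
    weighted_fractional_rank,
)
from .exceptions import DegenerateOutcomeError, SeparationError

__all__ = [
    "ProbitRegression",
    "ErreygersDecomposition",
    "partial_effects_at_means",
    "covariate_concentration",
    "significance_stars",
]

_NORM_PDF_C = 1.0 / np.sqrt(2.0 * np.pi)


def _norm_pdf(x):
    return _NORM_PDF_C * np.exp(-0.5 * x * x)


def _mills(eta: np.ndarray) -> np.ndarray:
    """phi(eta) / Phi(eta), computed in log space to survive deep tails."""
    return np.exp(np.log(_NORM_PDF_C) - 0.5 * eta * eta - log_ndtr(eta))


class ProbitRegression(BaseEstimator):
    """Weighted probit fitted by Newton's method with observed information.

    Maximizes ``sum_i w_i [y_i log Phi(x_i'b) + (1 - y_i) log(1 - Phi(x_i'b))]``.
    The coefficient covariance is the inverse observed information at the
    optimum (weights treated as frequency-type weights).

    Attributes
    ----------
    params_ : ndarray            full coefficient vector (intercept first if fitted)
    coef_, intercept_ : sklearn-style views of ``params_``
    cov_params_ : ndarray        inverse observed information
    bse_ : ndarray               coefficient standard errors
    pvalues_ : ndarray           two-sided normal p-values
    log_likelihood_ : float
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, fit_intercept: bool = True, tol: float = 1e-10,
                 grad_tol: float = 1e-6, max_iter: int = 100):
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    def _design(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y, sample_weight=None):
        y = np.asarray(y, dtype=float)
        if not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("outcomes must be binary 0/1")
        if y.min() == y.max():
            raise DegenerateOutcomeError("outcome has no variation (all 0s or all 1s)")
        n = y.size
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if np.any(w <= 0):
            raise ValueError("sample_weight must be positive")
        Xd = self._design(X)
        if Xd.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        p = Xd.shape[1]
        if np.linalg.matrix_rank(Xd) < p:
            raise ValueError("design matrix is rank deficient")

        beta = np.zeros(p)
        W = w.sum()

        def loglik(b):
            eta = Xd @ b
            return float(w @ (y * log_ndtr(eta) + (1 - y) * log_ndtr(-eta)))

        ll = loglik(beta)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = Xd @ beta
            lam_pos = _mills(eta)       # phi/Phi
            lam_neg = _mills(-eta)      # phi/(1-Phi)
            g = y * lam_pos - (1 - y) * lam_neg          # generalized residual
            score = Xd.T @ (w * g)
            h = g * (g + eta)                            # -d2 loglik_i / d eta2
            info = (Xd * (w * h)[:, None]).T @ Xd        # observed information
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as err:
                raise SeparationError(
                    "singular information matrix; data may be separated") from err
            # step-halving line search on the log likelihood
            t = 1.0
            for _ in range(40):
                candidate = beta + t * step
                ll_new = loglik(candidate)
                if ll_new >= ll - 1e-12:
                    break
                t /= 2.0
            beta, ll_prev, ll = candidate, ll, ll_new
            if np.max(np.abs(beta)) > 1e6:
                raise SeparationError(
                    "coefficients diverging; a covariate perfectly predicts the outcome")
            grad_norm = float(np.max(np.abs(score))) / W
            if abs(ll - ll_prev) <= self.tol * (abs(ll_prev) + 1e-12) and \
                    grad_norm < self.grad_tol:
                converged = True
                break

        eta = Xd @ beta
        # perfect separation: every point classified correctly with near-certain
        # fitted probabilities (the likelihood supremum 0 is not attained)
        if np.all((eta > 0) == (y == 1)) and np.min(np.abs(eta)) > 5.0:
            raise SeparationError(
                "a linear combination of covariates perfectly separates the "
                "outcomes; probit coefficients are not identified")
        g = y * _mills(eta) - (1 - y) * _mills(-eta)
        h = g * (g + eta)
        info = (Xd * (w * h)[:, None]).T @ Xd
        self.params_ = beta
        self.cov_params_ = np.linalg.inv(info)
        self.bse_ = np.sqrt(np.diag(self.cov_params_))
        self.pvalues_ = 2.0 * stats.norm.sf(np.abs(beta) / self.bse_)
        self.log_likelihood_ = ll
        self.converged_ = converged
        self.gradient_norm_ = float(np.max(np.abs(Xd.T @ (w * g)))) / W
        self.n_iter_ = it
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(beta[0]), beta[1:].copy()
        else:
            self.intercept_, self.coef_ = 0.0, beta.copy()
        self.n_features_in_ = p - int(self.fit_intercept)
        return self

    def predict_linear(self, X) -> np.ndarray:
        return self._design(X) @ self.params_

    def predict_proba_1(self, X) -> np.ndarray:
        """P(y = 1 | x) = Phi(x'b)."""
        return ndtr(self.predict_linear(X))

    def generalized_residuals(self, X, y) -> np.ndarray:
        """First-order (score) residuals ``y phi/Phi - (1-y) phi/(1-Phi)``."""
        eta = self.predict_linear(X)
        y = np.asarray(y, dtype=float)
        return y * _mills(eta) - (1 - y) * _mills(-eta)


def partial_effects_at_means(params: np.ndarray, covariate_means: np.ndarray) -> np.ndarray:
    """Probit partial effects at the sample means: ``b_k * phi(xbar'b)``.

    Applied uniformly to continuous and indicator regressors, so that the
    decomposition's elasticity ``b_k^m * xbar_k`` is exact for the
    linearization at the means.
    """
    params = np.asarray(params, dtype=float)
    means = np.asarray(covariate_means, dtype=float)
    if params.shape != means.shape:
        raise ValueError("covariate_means must be conformable with the coefficients")
    return params * _norm_pdf(float(means @ params))


def covariate_concentration(design, ranks, weights=None) -> np.ndarray:
    """Standard concentration index of each design column over the income ranks.

    ``CI_k = 2 cov_w(x_k, R) / xbar_k``; zero-mean columns (for which the
    relative index is undefined) yield NaN.
    """
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    r = np.asarray(ranks, dtype=float)
    n = X.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    wn = w / w.sum()
    means = wn @ X
    cov = ((X - means) * (wn * (r - wn @ r))[:, None]).sum(axis=0)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    nonzero = np.abs(means) > 1e-12 * scale
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = np.where(nonzero, 2.0 * cov / np.where(nonzero, means, 1.0), np.nan)
    return ci


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


class ErreygersDecomposition(BaseEstimator):
    """Decompose the Erreygers-corrected CI of a binary outcome by covariate.

    Parameters
    ----------
    fit_intercept : bool, default True
        Include an intercept in the probit (it never contributes to measured
        inequality: a constant has a zero concentration index).
    discrete_dummies : bool, default False
        If True, use discrete-change effects at the means for binary columns
        instead of the density-scaled derivative (optional variant).

    Attributes (after ``fit``)
    --------------------------
    probit_ : ProbitRegression       fitted utilization model
    table_ : pandas.DataFrame        one row per covariate: coefficient,
        std_error, p_value, stars, partial_effect, mean, elasticity, ci_k,
        contribution
    total_corrected_ci_ : float      Erreygers-corrected CI of the outcome
    total_se_ : float                its robust standard error
    residual_ : float                E - sum of contributions (exact by construction)
    residual_generalized_ : float    4 x generalized CI of y - Phi(x'b)
    """

    def __init__(self, fit_intercept: bool = True, discrete_dummies: bool = False):
        self.fit_intercept = fit_intercept
        self.discrete_dummies = discrete_dummies

    def fit(self, X, y, sample_weight=None, ranking_variable=None, ranks=None,
            feature_names=None):
        """Fit the probit and decompose inequality in ``y`` over income ranks.

        Either ``ranking_variable`` (e.g. equivalised income; ranks are
        computed) or precomputed ``ranks`` must be supplied.
        """
        if isinstance(X, pd.DataFrame):
            if feature_names is None:
                feature_names = list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        n, p = X.shape
        y = np.asarray(y, dtype=float)
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if ranks is None:
            if ranking_variable is None:
                raise ValueError("supply ranking_variable or precomputed ranks")
            ranks = weighted_fractional_rank(ranking_variable, w)
        ranks = np.asarray(ranks, dtype=float)
        if feature_names is None:
            feature_names = [f"x{k}" for k in range(p)]

        probit = ProbitRegression(fit_intercept=self.fit_intercept).fit(
            X, y, sample_weight=w)
        self.probit_ = probit

        Xd = probit._design(X)
        wn = w / w.sum()
        means = wn @ Xd
        pem = partial_effects_at_means(probit.params_, means)
        if self.discrete_dummies:
            pem = self._discrete_effects(Xd, means, probit.params_, pem)
        elasticity = pem * means
        ci_k = covariate_concentration(Xd, ranks, w)
        contribution = np.where(np.isnan(ci_k), 0.0, 4.0 * elasticity * ci_k)

        sample = RankedSample.from_ranks(y, ranks, w)
        total = erreygers_index(sample)
        self.total_corrected_ci_ = total.corrected_value
        self.total_se_ = total.standard_error
        self.concentration_result_ = total

        names = (["intercept"] if self.fit_intercept else []) + list(feature_names)
        keep = slice(1, None) if self.fit_intercept else slice(None)
        self.table_ = pd.DataFrame({
            "covariate": names[keep],
            "coefficient": probit.params_[keep],
            "std_error": probit.bse_[keep],
            "p_value": probit.pvalues_[keep],
            "stars": [significance_stars(pv) for pv in probit.pvalues_[keep]],
            "partial_effect": pem[keep],
            "mean": means[keep],
            "elasticity": elasticity[keep],
            "ci_k": ci_k[keep],
            "contribution": contribution[keep],
        })
        explained = float(np.nansum(contribution))
        self.residual_ = self.total_corrected_ci_ - explained
        eps = y - probit.predict_proba_1(X)
        self.residual_generalized_ = 4.0 * generalized_ci(
            RankedSample.from_ranks(eps, ranks, w))
        return self

    def _discrete_effects(self, Xd, means, params, pem):
        """Discrete-change partial effects at the means for binary columns."""
        pem = pem.copy()
        eta_bar = float(means @ params)
        for k in range(Xd.shape[1]):
            col = Xd[:, k]
            if set(np.unique(col)) <= {0.0, 1.0} and col.min() != col.max():
                eta0 = eta_bar - means[k] * params[k]
                pem[k] = ndtr(eta0 + params[k]) - ndtr(eta0)
        return pem
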