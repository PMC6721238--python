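"""Banded-income imputation and income adjustment.

Survey income is often recorded only as one of a small number of currency
bands.  To rank respondents on a continuous living-standards variable, a
weighted interval regression (interval-censored Gaussian maximum likelihood)
is fitted on the log-income scale: a respondent reporting band ``(l, u]``
contributes ``log[ Phi((log u - x'g)/s) - Phi((log l - x'g)/s) ]`` to the
log likelihood, with the bottom band's lower bound mapped to one currency
unit (``log 1 = 0``) and an open top band contributing the upper survival
term.  Point predictions ``exp(x'g)``, floored at one currency unit, replace
the bands.

The predicted income is then converted to equivalent individual income with
the modified OECD equivalence scale (divisor ``1 + 0.5 per extra adult +
0.3 per child``) and rescaled to a base year's price level with consumer
price indices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import NonIdentifiableScaleError

__all__ = [
    "IntervalIncomeRegressor",
    "equivalise_income",
    "oecd_equivalence_divisor",
    "rescale_to_base_year",
    "load_cpi_table",
]

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _log_interval_prob(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) computed stably for a < b (b may be +inf)."""
    # work on the side where the CDF difference is best conditioned
    flip = a > -b  # right tail: use symmetry Phi(b)-Phi(a) = Phi(-a)-Phi(-b)
    lo = np.where(flip, -b, a)
    hi = np.where(flip, -a, b)
    log_hi = log_ndtr(hi)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_lo = log_ndtr(lo)
        out = log_hi + np.log1p(-np.exp(log_lo - log_hi))
    out = np.where(np.isneginf(lo), log_hi, out)
    return out


class IntervalIncomeRegressor(RegressorMixin, BaseEstimator):
    """Weighted interval regression for band-censored income.

    Parameters
    ----------
    fit_intercept : bool, default True
        Prepend an intercept column to the design.
    log_scale : bool, default True
        Model log income (log-normal bands); if False, model income levels
        directly (normal bands).
    income_floor : float, default 1.0
        Lower clamp for predictions, in currency units; also the value the
        bottom band's zero lower bound is mapped to on the log scale.
    tol : float, default 1e-10
        Relative log-likelihood convergence tolerance.
    grad_tol : float, default 1e-6
        Max-norm tolerance for the gradient of the mean log likelihood.
    max_iter : int, default 200
        Maximum quasi-Newton iterations.

    Attributes
    ----------
    coef_ : ndarray
        Covariate coefficients on the (log-)income scale.
    intercept_ : float
        Intercept (0.0 when ``fit_intercept=False``).
    sigma_ : float
        Residual scale of the latent (log-)income.
    log_likelihood_ : float
        Weighted log likelihood at the optimum.
    coef_bse_, intercept_bse_, sigma_bse_ :
        Standard errors from the inverse observed information.
    converged_ : bool
    n_iter_ : int
    """

    def __init__(self, fit_intercept: bool = True, log_scale: bool = True,
                 income_floor: float = 1.0, tol: float = 1e-10,
                 grad_tol: float = 1e-6, max_iter: int = 200):
        self.fit_intercept = fit_intercept
        self.log_scale = log_scale
        self.income_floor = income_floor
        self.tol = tol
        self.grad_tol = grad_tol
        self.max_iter = max_iter

    # -- internal -----------------------------------------------------------

    def _design(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
        return X

    def fit(self, X, y, sample_weight=None):
        """Fit by maximum likelihood.

        Parameters
        ----------
        X : array-like of shape (n, p)
            Covariates (e.g. age indicators, education, region).
        y : array-like of shape (n, 2)
            Band bounds ``(lower, upper)`` in currency units; the upper bound
            of the open top band may be ``np.inf``; a zero (or sub-floor)
            lower bound is clamped to ``income_floor``.
        sample_weight : array-like, optional
            Positive sampling weights.
        """
        bounds = np.asarray(y, dtype=float)
        if bounds.ndim != 2 or bounds.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of (lower, upper) band bounds")
        lower, upper = bounds[:, 0], bounds[:, 1]
        if np.any(lower >= upper):
            raise ValueError("each lower bound must be strictly below its upper bound")
        n = lower.size
        if np.unique(bounds, axis=0).shape[0] < 2:
            raise NonIdentifiableScaleError(
                "all observations fall in a single band; scale not identified")
        w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, float)
        if np.any(w <= 0):
            raise ValueError("sample_weight must be positive")

        Xd = self._design(X)
        if Xd.shape[0] != n:
            raise ValueError("X and y have inconsistent lengths")
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise ValueError("design matrix is rank deficient")
        p = Xd.shape[1]

        if self.log_scale:
            lo = np.log(np.clip(lower, self.income_floor, None))
            hi = np.where(np.isinf(upper), np.inf, np.log(np.maximum(upper, 1e-300)))
        else:
            lo, hi = lower, upper

        wn = w / w.sum()  # mean-scale likelihood keeps tolerances size-free

        def negloglik_and_grad(theta):
            gamma, log_sigma = theta[:p], theta[p]
            sigma = np.exp(log_sigma)
            mu = Xd @ gamma
            a = (lo - mu) / sigma
            b = np.where(np.isinf(hi), np.inf, (hi - mu) / sigma)
            logp = _log_interval_prob(a, b)
            nll = -float(wn @ logp)

            phi_a = np.exp(-0.5 * a * a) / _SQRT2PI
            finite_b = np.isfinite(b)
            bb = np.where(finite_b, b, 0.0)
            phi_b = np.where(finite_b, np.exp(-0.5 * bb * bb) / _SQRT2PI, 0.0)
            prob = np.exp(logp)
            prob = np.maximum(prob, 1e-300)
            dl_dmu = (phi_a - phi_b) / (sigma * prob)
            a_phi_a = a * phi_a
            b_phi_b = np.where(finite_b, bb * phi_b, 0.0)
            dl_dlogsigma = (a_phi_a - b_phi_b) / prob
            grad = np.empty(p + 1)
            grad[:p] = -(Xd.T @ (wn * dl_dmu))
            grad[p] = -float(wn @ dl_dlogsigma)
            return nll, grad

        # starts: least squares on band midpoints (top band: lower + sigma0)
        mid = np.where(np.isfinite(hi), (lo + np.minimum(hi, 1e300)) / 2.0, lo + 0.5)
        gamma0, *_ = np.linalg.lstsq(Xd * np.sqrt(wn)[:, None],
                                     mid * np.sqrt(wn), rcond=None)
        resid0 = mid - Xd @ gamma0
        sigma0 = max(np.sqrt(wn @ resid0**2), 1e-2)
        theta0 = np.concatenate([gamma0, [np.log(sigma0)]])

        res = optimize.minimize(
            negloglik_and_grad, theta0, jac=True, method="BFGS",
            options={"gtol": self.grad_tol, "maxiter": self.max_iter})

        theta = res.x
        gamma, sigma = theta[:p], float(np.exp(theta[p]))

        # observed information: central differences on the analytic gradient
        # of the mean-scale NLL; total-likelihood covariance = (W * H)^-1
        hess = np.empty((p + 1, p + 1))
        eps_fd = 1e-5 * np.maximum(np.abs(theta), 1.0)
        for j in range(p + 1):
            dj = np.zeros(p + 1)
            dj[j] = eps_fd[j]
            _, g_plus = negloglik_and_grad(theta + dj)
            _, g_minus = negloglik_and_grad(theta - dj)
            hess[:, j] = (g_plus - g_minus) / (2.0 * eps_fd[j])
        hess = (hess + hess.T) / 2.0
        try:
            cov = np.linalg.inv(hess * w.sum())
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        except np.linalg.LinAlgError:
            se = np.full(p + 1, np.nan)
        if self.fit_intercept:
            self.intercept_, self.coef_ = float(gamma[0]), gamma[1:].copy()
            self.intercept_bse_, self.coef_bse_ = float(se[0]), se[1:p].copy()
        else:
            self.intercept_, self.coef_ = 0.0, gamma.copy()
            self.intercept_bse_, self.coef_bse_ = 0.0, se[:p].copy()
        self.sigma_ = sigma
        self.sigma_bse_ = sigma * float(se[p])  # delta method from log-scale
        self.log_likelihood_ = -res.fun * w.sum()
        grad_norm = float(np.max(np.abs(res.jac)))
        self.converged_ = bool(res.success or grad_norm < 10 * self.grad_tol)
        self.gradient_norm_ = grad_norm
        self.n_iter_ = int(res.nit)
        self.n_features_in_ = Xd.shape[1] - int(self.fit_intercept)
        return self

    def predict_linear(self, X) -> np.ndarray:
        """Linear predictor ``x'g`` on the latent (log-)income scale."""
        Xd = self._design(X)
        if Xd.shape[1] != self.coef_.size + int(self.fit_intercept):
            raise ValueError("X has a different number of features than at fit time")
        gamma = (np.concatenate([[self.intercept_], self.coef_])
                 if self.fit_intercept else self.coef_)
        return Xd @ gamma

    def predict(self, X) -> np.ndarray:
        """Predicted income in currency units, clamped below at the floor."""
        eta = self.predict_linear(X)
        income = np.exp(eta) if self.log_scale else eta
        return np.maximum(income, self.income_floor)

    def predict_conditional(self, X, y) -> np.ndarray:
        """Expected (log-)income given covariates AND the observed band.

        For a band ``(l, u]`` the truncated-normal mean on the latent scale is
        ``mu + sigma (phi(a) - phi(b)) / (Phi(b) - Phi(a))`` with
        ``a = (log l - mu)/sigma``; this keeps the within-band information the
        marginal prediction discards and is the prediction the ranking stage
        uses.  Returned in currency units, clamped at the floor.
        """
        bounds = np.asarray(y, dtype=float)
        lower, upper = bounds[:, 0], bounds[:, 1]
        mu = self.predict_linear(X)
        if self.log_scale:
            lo = np.log(np.clip(lower, self.income_floor, None))
            hi = np.where(np.isinf(upper), np.inf, np.log(np.maximum(upper, 1e-300)))
        else:
            lo, hi = lower, upper
        a = (lo - mu) / self.sigma_
        b = np.where(np.isinf(hi), np.inf, (hi - mu) / self.sigma_)
        phi_a = np.exp(-0.5 * a * a) / _SQRT2PI
        phi_b = np.where(np.isfinite(b), np.exp(-0.5 * np.minimum(b, 1e9)**2), 0.0) / _SQRT2PI
        prob = np.maximum(np.exp(_log_interval_prob(a, b)), 1e-300)
        latent = mu + self.sigma_ * (phi_a - phi_b) / prob
        income = np.exp(latent) if self.log_scale else latent
        return np.maximum(income, self.income_floor)


def oecd_equivalence_divisor(adults, children) -> np.ndarray:
    """Modified OECD scale: 1 for the first adult, +0.5 per extra adult, +0.3 per child."""
    adults = np.asarray(adults, dtype=float)
    children = np.asarray(children, dtype=float)
    if np.any(adults < 1):
        raise ValueError("each household must contain at least one adult")
    if np.any(children < 0):
        raise ValueError("children count cannot be negative")
    return 1.0 + 0.5 * (adults - 1.0) + 0.3 * children


def equivalise_income(income, adults, children):
    """Household income to equivalent individual income (modified OECD scale)."""
    return np.asarray(income, dtype=float) / oecd_equivalence_divisor(adults, children)


def rescale_to_base_year(income, cpi_survey_year: float, cpi_base_year: float):
    """Rescale income to the base year's price level: ``income * cpi_base / cpi_survey``."""
    if cpi_survey_year <= 0 or cpi_base_year <= 0:
        raise ValueError("consumer price indices must be positive")
    return np.asarray(income, dtype=float) * (cpi_base_year / cpi_survey_year)


def load_cpi_table(path) -> dict[int, float]:
    """Read a two-column delimited CPI table (year, index value) into a dict."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("CPI table needs two columns: year, index value")
    years = df.iloc[:, 0].astype(int)
    values = df.iloc[:, 1].astype(float)
    if np.any(values <= 0):
        raise ValueError("consumer price indices must be positive")
    return dict(zip(years, values))
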