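"""Weighted concentration indices for income-related health inequality.

The concentration index (CI) of an outcome ``y`` over a living-standards
ranking variable (here equivalised income) is

    CI = 2 cov_w(y_i, R_i) / ybar,

where ``R_i`` is the weighted fractional rank of individual *i* in the income
distribution and ``ybar`` the weighted mean outcome.  A positive CI means the
outcome is concentrated among the better-off ("pro-rich").  For bounded —
in particular binary — outcomes the Erreygers-corrected index

    E = 4 ybar / (y_max - y_min) * CI

restores the ±1 bounds under perfect concentration and mirror symmetry
between health and ill-health codings.

Standard errors come from the "convenient regression" formulation: the CI is
the slope of a weighted least-squares regression of the transformed outcome
``2 var_w(R) y_i / ybar`` on the fractional rank, so the
heteroskedasticity-robust slope standard error is the index standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    UndefinedIndexError,
)

__all__ = [
    "RankedSample",
    "ConcentrationResult",
    "IndexComparison",
    "weighted_fractional_rank",
    "concentration_index",
    "erreygers_correct",
    "erreygers_index",
    "generalized_ci",
    "ci_standard_error",
    "compare_indices",
]


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,):
        raise ValueError(f"weights must have shape ({n},), got {w.shape}")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be positive and finite")
    return w


def weighted_fractional_rank(ranking_variable, weights=None) -> np.ndarray:
    """Weighted fractional ranks in (0, 1), returned in the input order.

    After a stable sort by the ranking variable, unit *i* receives

        R_i = (cumulative weight of strictly preceding units + w_i / 2) / W.

    Tied values all receive the midpoint rank of their tie group's total
    weight mass, which equals the weighted average of the ranks the group
    members would receive in any within-group order.  The weighted mean of
    the ranks is exactly 0.5.

    Parameters
    ----------
    ranking_variable : array-like
        Living-standards variable (e.g. equivalised income).
    weights : array-like, optional
        Positive sampling weights; defaults to equal weights.

    Returns
    -------
    ndarray of ranks, same length and order as the input.
    """
    x = np.asarray(ranking_variable, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("ranking_variable must be a non-empty 1-d array")
    w = _as_weights(weights, x.size)

    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    total = ws.sum()
    cum_before = np.concatenate(([0.0], np.cumsum(ws)[:-1]))
    ranks_sorted = (cum_before + ws / 2.0) / total

    # replace within-tie ranks by the tie group's weight-mass midpoint
    boundaries = np.concatenate(([True], xs[1:] != xs[:-1]))
    group = np.cumsum(boundaries) - 1
    n_groups = group[-1] + 1
    gw = np.bincount(group, weights=ws, minlength=n_groups)
    g_start = np.concatenate(([0.0], np.cumsum(gw)[:-1]))
    ranks_sorted = (g_start[group] + gw[group] / 2.0) / total

    out = np.empty_like(ranks_sorted)
    out[order] = ranks_sorted
    return out


@dataclass(frozen=True)
class RankedSample:
    """An outcome vector with weights and income fractional ranks."""

    outcome: np.ndarray
    ranking_variable: np.ndarray
    weights: np.ndarray
    ranks: np.ndarray

    @classmethod
    def from_arrays(cls, outcome, ranking_variable, weights=None) -> "RankedSample":
        y = np.asarray(outcome, dtype=float)
        x = np.asarray(ranking_variable, dtype=float)
        if y.shape != x.shape or y.ndim != 1:
            raise ValueError("outcome and ranking_variable must be equal-length 1-d arrays")
        w = _as_weights(weights, y.size)
        return cls(outcome=y, ranking_variable=x, weights=w,
                   ranks=weighted_fractional_rank(x, w))

    @classmethod
    def from_ranks(cls, values, ranks, weights=None) -> "RankedSample":
        """Attach precomputed fractional ranks to a value vector."""
        v = np.asarray(values, dtype=float)
        r = np.asarray(ranks, dtype=float)
        if v.shape != r.shape or v.ndim != 1:
            raise ValueError("values and ranks must be equal-length 1-d arrays")
        w = _as_weights(weights, v.size)
        return cls(outcome=v, ranking_variable=r, weights=w, ranks=r)

    @property
    def n(self) -> int:
        return self.outcome.size


@dataclass(frozen=True)
class ConcentrationResult:
    """Point estimates for a concentration index and its Erreygers correction.

    ``standard_error`` refers to ``index_value`` as returned by
    :func:`concentration_index`, and to ``corrected_value`` after
    :func:`erreygers_correct`.
    """

    mean_outcome: float
    index_value: float
    corrected_value: float
    outcome_min: float
    outcome_max: float
    standard_error: float
    n: int


@dataclass(frozen=True)
class IndexComparison:
    """Two-sample comparison of (corrected) concentration indices."""

    difference: float
    difference_se: float
    z_statistic: float
    p_value: float


def _weighted_cov(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wn = w / w.sum()
    am = wn @ a
    bm = wn @ b
    return float(wn @ ((a - am) * (b - bm)))


def generalized_ci(sample: RankedSample) -> float:
    """Generalized concentration index: ``2 cov_w(values, R)``, no mean scaling.

    Used for the residual term of the inequality decomposition.
    """
    return 2.0 * _weighted_cov(sample.outcome, sample.ranks, sample.weights)


def concentration_index(sample: RankedSample, compute_se: bool = True) -> ConcentrationResult:
    """Standard (relative) concentration index ``2 cov_w(y, R) / ybar``.

    Raises
    ------
    UndefinedIndexError
        If the weighted mean outcome is zero (index undefined).
    """
    w = sample.weights
    ybar = float((w / w.sum()) @ sample.outcome)
    if ybar == 0.0:
        raise UndefinedIndexError("outcome mean is zero; concentration index undefined")
    ci = generalized_ci(sample) / ybar
    se = ci_standard_error(sample) if compute_se and sample.n >= 3 else float("nan")
    return ConcentrationResult(
        mean_outcome=ybar,
        index_value=ci,
        corrected_value=float("nan"),
        outcome_min=float(sample.outcome.min()),
        outcome_max=float(sample.outcome.max()),
        standard_error=se,
        n=sample.n,
    )


def erreygers_correct(result: ConcentrationResult,
                      outcome_min: float = 0.0,
                      outcome_max: float = 1.0) -> ConcentrationResult:
    """Apply Erreygers' bounded-outcome correction ``E = 4 ybar CI / (max - min)``.

    For a binary utilization outcome the bounds are fixed at (0, 1)
    regardless of the observed minimum and maximum, so that E attains ±1
    under perfect concentration.  The standard error is mapped through the
    same scaling (delta method, mean treated as fixed).
    """
    if not outcome_max > outcome_min:
        raise ValueError("outcome_max must exceed outcome_min")
    scale = 4.0 * result.mean_outcome / (outcome_max - outcome_min)
    return replace(
        result,
        corrected_value=scale * result.index_value,
        outcome_min=outcome_min,
        outcome_max=outcome_max,
        standard_error=abs(scale) * result.standard_error,
    )


def erreygers_index(sample: RankedSample,
                    outcome_min: float = 0.0,
                    outcome_max: float = 1.0,
                    compute_se: bool = True) -> ConcentrationResult:
    """Convenience wrapper: concentration index plus Erreygers correction."""
    return erreygers_correct(concentration_index(sample, compute_se=compute_se),
                             outcome_min, outcome_max)


def ci_standard_error(sample: RankedSample, corrected: bool = False,
                      outcome_min: float = 0.0, outcome_max: float = 1.0) -> float:
    """Heteroskedasticity-robust standard error of the (corrected) index.

    Runs the convenient regression of ``2 var_w(R) y / ybar`` on the
    fractional rank with the sampling weights and returns the HC1-robust
    standard error of the rank slope; with ``corrected=True`` the error is
    scaled by ``4 ybar / (outcome_max - outcome_min)`` to refer to the
    Erreygers-corrected index.
    """
    y, r, w = sample.outcome, sample.ranks, sample.weights
    n = y.size
    if n < 3:
        raise InsufficientDataError("standard error requires at least 3 observations")
    wn = w / w.sum()
    ybar = float(wn @ y)
    if ybar == 0.0:
        raise UndefinedIndexError("outcome mean is zero; concentration index undefined")
    var_r = _weighted_cov(r, r, w)
    ystar = 2.0 * var_r * y / ybar

    # weighted least squares of ystar on [1, r]; HC1 sandwich for the slope
    X = np.column_stack([np.ones(n), r])
    WX = X * w[:, None]
    bread = np.linalg.inv(X.T @ WX)
    beta = bread @ (WX.T @ ystar)
    resid = ystar - X @ beta
    meat = (WX * (resid**2)[:, None]).T @ WX
    cov = bread @ meat @ bread * (n / (n - 2))
    se = float(np.sqrt(cov[1, 1]))
    if corrected:
        se *= 4.0 * ybar / (outcome_max - outcome_min)
    return se


def compare_indices(a: ConcentrationResult, b: ConcentrationResult) -> IndexComparison:
    """Two-sample z-test for the difference of corrected indices, ``b - a``.

    The samples are assumed independent (e.g. two cross-sectional survey
    waves), so the standard error of the difference combines as
    ``sqrt(se_a**2 + se_b**2)``.
    """
    if a.standard_error == 0.0 and b.standard_error == 0.0:
        raise UndefinedIndexError("both standard errors are zero; test undefined")
    diff = b.corrected_value - a.corrected_value
    se = float(np.hypot(a.standard_error, b.standard_error))
    z = diff / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return IndexComparison(difference=diff, difference_se=se, z_statistic=z, p_value=p)
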