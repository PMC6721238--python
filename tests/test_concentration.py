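"""Concentration index machinery: ranks, CI, Erreygers correction, SEs."""

import numpy as np
import pytest

from healthineq.concentration import (
    RankedSample,
    ci_standard_error,
    compare_indices,
    concentration_index,
    erreygers_correct,
    erreygers_index,
    generalized_ci,
    weighted_fractional_rank,
)
from healthineq.exceptions import InsufficientDataError, UndefinedIndexError


def pairwise_ci_oracle(y, x, w=None):
    """Brute-force double-sum concentration index.

    CI = sum_ij w_i w_j (y_i - y_j) sign(x_i - x_j) / (2 W^2 ybar),
    an independent route that never forms fractional ranks.
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    W = w.sum()
    ybar = (w @ y) / W
    s = np.sign(x[:, None] - x[None, :])
    total = (w[:, None] * w[None, :] * (y[:, None] - y[None, :]) * s).sum()
    return total / (2.0 * W**2 * ybar)


class TestFractionalRank:
    @pytest.mark.parametrize("values, weights, expected", [
        ([5.0], [1.0], [0.5]),
        ([1, 2, 3, 4], None, [0.125, 0.375, 0.625, 0.875]),
        ([1, 2, 3], [1, 2, 1], [0.125, 0.5, 0.875]),
    ])
    def test_known_midpoint_ranks(self, values, weights, expected):
        np.testing.assert_allclose(
            weighted_fractional_rank(values, weights), expected, atol=1e-15)

    def test_ties_share_group_midpoint(self):
        r = weighted_fractional_rank([2, 1, 2, 3], [1, 1, 1, 1])
        np.testing.assert_allclose(r, [0.5, 0.125, 0.5, 0.875])

    def test_ranks_returned_in_input_order_and_monotone(self, rng):
        x = rng.normal(size=200)
        r = weighted_fractional_rank(x, rng.uniform(0.5, 2.0, size=200))
        assert np.all((r > 0) & (r < 1))
        order = np.argsort(x)
        assert np.all(np.diff(r[order]) >= 0)

    def test_weighted_mean_is_half(self, rng):
        w = rng.uniform(0.1, 5.0, size=137)
        x = rng.integers(0, 10, size=137).astype(float)  # plenty of ties
        r = weighted_fractional_rank(x, w)
        assert abs(np.average(r, weights=w) - 0.5) < 1e-12

    def test_rejects_empty_and_nonpositive_weights(self):
        with pytest.raises(ValueError):
            weighted_fractional_rank([])
        with pytest.raises(ValueError):
            weighted_fractional_rank([1.0, 2.0], [1.0, 0.0])


class TestConcentrationIndex:
    def test_constant_outcome_gives_zero_index(self):
        s = RankedSample.from_arrays([3.0] * 10, np.arange(10))
        res = concentration_index(s)
        assert res.index_value == pytest.approx(0.0, abs=1e-15)
        assert res.standard_error == pytest.approx(0.0, abs=1e-12)

    def test_two_person_perfect_concentration(self):
        # poorer has y=0, richer y=1: ranks (0.25, 0.75), cov = 0.125, CI = 0.5
        s = RankedSample.from_arrays([0.0, 1.0], [100.0, 200.0])
        res = concentration_index(s, compute_se=False)
        assert res.mean_outcome == pytest.approx(0.5)
        assert res.index_value == pytest.approx(0.5)
        corrected = erreygers_correct(res, 0.0, 1.0)
        assert corrected.corrected_value == pytest.approx(1.0)

    def test_all_zero_outcome_raises(self):
        s = RankedSample.from_arrays([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])
        with pytest.raises(UndefinedIndexError):
            concentration_index(s)

    def test_matches_pairwise_oracle_weighted(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 60))
            y = rng.binomial(1, 0.5, size=n).astype(float)
            if y.sum() == 0:
                y[0] = 1.0
            x = rng.choice([1.0, 2.0, 3.0, 5.0, 8.0], size=n)  # with ties
            w = rng.uniform(0.2, 3.0, size=n)
            s = RankedSample.from_arrays(y, x, w)
            res = concentration_index(s, compute_se=False)
            assert res.index_value == pytest.approx(
                pairwise_ci_oracle(y, x, w), abs=1e-10)

    def test_weight_scale_invariance(self, rng):
        y = rng.binomial(1, 0.4, size=80).astype(float)
        y[0] = 1.0
        x = rng.normal(size=80)
        w = rng.uniform(0.5, 2.0, size=80)
        a = erreygers_index(RankedSample.from_arrays(y, x, w))
        b = erreygers_index(RankedSample.from_arrays(y, x, 7.3 * w))
        assert a.index_value == pytest.approx(b.index_value, abs=1e-12)
        assert a.corrected_value == pytest.approx(b.corrected_value, abs=1e-12)
        assert a.standard_error == pytest.approx(b.standard_error, abs=1e-12)

    def test_monotone_transform_of_ranking_variable(self, rng):
        y = rng.binomial(1, 0.5, size=60).astype(float)
        y[0] = 1.0
        x = rng.uniform(1.0, 9.0, size=60)
        a = concentration_index(RankedSample.from_arrays(y, x), compute_se=False)
        b = concentration_index(RankedSample.from_arrays(y, np.log(x)),
                                compute_se=False)
        assert a.index_value == pytest.approx(b.index_value, abs=1e-14)

    def test_reversal_antisymmetry(self, rng):
        y = rng.binomial(1, 0.5, size=75).astype(float)
        y[0] = 1.0
        x = rng.normal(size=75)
        a = erreygers_index(RankedSample.from_arrays(y, x), compute_se=False)
        b = erreygers_index(RankedSample.from_arrays(y, -x), compute_se=False)
        assert a.index_value == pytest.approx(-b.index_value, abs=1e-12)
        assert a.corrected_value == pytest.approx(-b.corrected_value, abs=1e-12)

    def test_binary_identity_e_equals_4_mean_ci(self, rng):
        y = rng.binomial(1, 0.3, size=120).astype(float)
        y[0] = 1.0
        s = RankedSample.from_arrays(y, rng.normal(size=120),
                                     rng.uniform(0.5, 2.0, size=120))
        res = erreygers_index(s, compute_se=False)
        assert res.corrected_value == pytest.approx(
            4.0 * res.mean_outcome * res.index_value, abs=1e-12)


class TestErreygers:
    def test_zero_maps_to_zero(self):
        s = RankedSample.from_arrays([1.0, 1.0], [1.0, 2.0])
        res = erreygers_correct(concentration_index(s, compute_se=False))
        assert res.corrected_value == 0.0

    def test_quarter_mean_identity_point(self, rng):
        # at ybar = 0.25 the Erreygers scaling 4*ybar equals 1, so E = CI
        y = np.array([1.0, 0.0, 0.0, 0.0] * 10)
        s = RankedSample.from_arrays(y, rng.permutation(40).astype(float))
        res = erreygers_index(s, compute_se=False)
        assert res.mean_outcome == pytest.approx(0.25)
        assert res.corrected_value == pytest.approx(res.index_value, abs=1e-14)

    def test_degenerate_bounds_rejected(self):
        s = RankedSample.from_arrays([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            erreygers_correct(concentration_index(s, compute_se=False), 0.3, 0.3)


class TestGeneralizedCI:
    def test_constant_values_give_zero(self):
        s = RankedSample.from_arrays([2.0] * 5, [1, 2, 3, 4, 5])
        assert generalized_ci(s) == pytest.approx(0.0, abs=1e-15)

    def test_values_equal_ranks_approach_one_sixth(self):
        # 2 Var(R) for uniform midpoint ranks -> 1/6 as n grows
        n = 20_000
        x = np.arange(n, dtype=float)
        s = RankedSample.from_arrays(x, x)
        s = RankedSample.from_arrays(s.ranks, x)  # outcome = the ranks
        assert generalized_ci(s) == pytest.approx(1.0 / 6.0, abs=1e-3)

    def test_sign_flips_under_rank_reversal(self, rng):
        v = rng.normal(size=50)
        x = rng.normal(size=50)
        a = generalized_ci(RankedSample.from_arrays(v, x))
        b = generalized_ci(RankedSample.from_arrays(v, -x))
        assert a == pytest.approx(-b, abs=1e-12)


class TestStandardError:
    def test_requires_three_observations(self):
        s = RankedSample.from_arrays([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(InsufficientDataError):
            ci_standard_error(s)

    def test_matches_convenient_regression_point_estimate(self, rng):
        # the WLS slope inside the SE routine must reproduce the covariance CI
        from healthineq.concentration import _weighted_cov

        for _ in range(25):
            n = int(rng.integers(5, 50))
            y = rng.binomial(1, 0.5, size=n).astype(float)
            if y.sum() == 0:
                y[0] = 1.0
            x = rng.normal(size=n)
            w = rng.uniform(0.2, 3.0, size=n)
            s = RankedSample.from_arrays(y, x, w)
            ci = concentration_index(s, compute_se=False).index_value
            wn = w / w.sum()
            ybar = wn @ y
            ystar = 2.0 * _weighted_cov(s.ranks, s.ranks, w) * y / ybar
            X = np.column_stack([np.ones(n), s.ranks])
            beta = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ ystar)
            assert ci == pytest.approx(beta[1], abs=1e-10)

    def test_half_weight_duplication_scales_se(self, rng):
        n = 400
        y = rng.binomial(1, 0.5, size=n).astype(float)
        x = rng.normal(size=n)
        s1 = RankedSample.from_arrays(y, x)
        se1 = ci_standard_error(s1)
        s2 = RankedSample.from_arrays(np.repeat(y, 2), np.repeat(x, 2),
                                      np.full(2 * n, 0.5))
        se2 = ci_standard_error(s2)
        # duplicates behave like a doubled independent sample: SE shrinks ~1/sqrt(2)
        assert se2 / se1 == pytest.approx(1.0 / np.sqrt(2.0), rel=0.02)


class TestCompareIndices:
    def _result(self, value, se):
        from healthineq.concentration import ConcentrationResult

        return ConcentrationResult(
            mean_outcome=0.5, index_value=np.nan, corrected_value=value,
            outcome_min=0.0, outcome_max=1.0, standard_error=se, n=1000)

    def test_difference_combines_independent_ses(self):
        cmp_ = compare_indices(self._result(0.0256, 0.0334),
                               self._result(-0.0098, 0.0304))
        assert cmp_.difference == pytest.approx(-0.0354, abs=5e-5)
        assert cmp_.difference_se == pytest.approx(0.0452, abs=5e-5)
        assert cmp_.p_value == pytest.approx(0.4328, abs=5e-4)

    def test_identical_results_give_zero_difference_p_one(self):
        cmp_ = compare_indices(self._result(0.1, 0.02), self._result(0.1, 0.02))
        assert cmp_.difference == 0.0
        assert cmp_.p_value == pytest.approx(1.0)

    def test_both_zero_ses_rejected(self):
        with pytest.raises(UndefinedIndexError):
            compare_indices(self._result(0.1, 0.0), self._result(0.2, 0.0))
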