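"""Censored likelihood terms against closed forms and adaptive quadrature."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from censba import BvnParams, PairedSample, Scenario, partition_sample
from censba.datamodel import CensoredPair, CensorStatus
from censba.likelihood import (
    DegenerateRegionError,
    Direction,
    censored_region_logprob,
    conditional_params,
    loglik,
    loglik_multi,
    loglik_single,
)

from conftest import (
    CX,
    CY,
    bvn_pdf,
    halfline_density_quadrature,
    obs,
    rect_prob_quadrature,
    xcens,
    ycens,
)


class TestConditionalParams:
    @pytest.mark.parametrize(
        "theta, given, direction, mean, var",
        [
            (BvnParams(0, 0, 1, 1, 0.9), 1.0, Direction.X_GIVEN_Y, 0.9, 0.19),
            (BvnParams(1, 2, 4, 9, 0.5), 5.0, Direction.X_GIVEN_Y, 2.0, 3.0),
            (BvnParams(1, 2, 4, 9, 0.5), 5.0, Direction.Y_GIVEN_X, 5.0, 6.75),
        ],
    )
    def test_closed_form(self, theta, given, direction, mean, var):
        cp = conditional_params(theta, given, direction)
        assert cp.mean == pytest.approx(mean, abs=1e-12)
        assert cp.var == pytest.approx(var, abs=1e-12)

    def test_independence_returns_marginal(self):
        th = BvnParams(1.0, -2.0, 4.0, 9.0, 0.0)
        cp = conditional_params(th, 17.0, Direction.X_GIVEN_Y)
        assert (cp.mean, cp.var) == (1.0, 4.0)


class TestCensoredRegionLogprob:
    def test_independent_quadrant(self, theta_std):
        th = BvnParams(0, 0, 1, 1, 0.0)
        lp = censored_region_logprob(th, 0.0, -math.inf, 0.0)
        assert lp == pytest.approx(math.log(0.25), rel=1e-10)

    def test_orthant_closed_form(self, theta_std):
        """P(X<=0, Y<=0) = 1/4 + arcsin(rho) / (2 pi) for standard margins."""
        expected = 0.25 + math.asin(0.9) / (2 * math.pi)
        lp = censored_region_logprob(theta_std, 0.0, -math.inf, 0.0)
        assert math.exp(lp) == pytest.approx(expected, rel=1e-8)
        assert math.exp(lp) == pytest.approx(0.428217, abs=5e-7)

    def test_zero_measure_interval_is_degenerate(self, theta_std):
        with pytest.raises(DegenerateRegionError):
            censored_region_logprob(theta_std, 0.0, 0.3, 0.3)

    @pytest.mark.parametrize(
        "x_upper, y_lower, y_upper",
        [(0.0, -math.inf, 0.0), (-0.8, -math.inf, -0.5), (0.5, -1.0, 0.7), (-1.0, -0.5, 0.1)],
    )
    def test_matches_2d_quadrature(self, theta_std, x_upper, y_lower, y_upper):
        lp = censored_region_logprob(theta_std, x_upper, y_lower, y_upper)
        oracle = rect_prob_quadrature(theta_std, x_upper, y_lower, y_upper)
        assert math.exp(lp) == pytest.approx(oracle, rel=1e-6)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        rho=st.floats(-0.99, 0.99),
        a=st.floats(-2, 2),
        b1=st.floats(-2, 0),
        width=st.floats(0.1, 3),
    )
    def test_widening_never_decreases_probability(self, rho, a, b1, width):
        th = BvnParams(0.0, 0.0, 1.0, 1.0, rho)
        narrow = censored_region_logprob(th, a, b1, b1 + width)
        wide = censored_region_logprob(th, a, b1 - 0.5, b1 + width + 0.5)
        assert wide >= narrow - 1e-12


class TestLoglikSingle:
    def test_uncensored_equals_sum_of_bivariate_logdensities(self, theta_std):
        rng = np.random.default_rng(0)
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=40)
        s = PairedSample(tuple(obs(float(x), float(y)) for x, y in z))
        ll = loglik_single(theta_std, partition_sample(s), None, None)
        expected = sum(math.log(bvn_pdf(x, y, theta_std)) for x, y in z)
        assert ll.value == pytest.approx(expected, abs=1e-8)

    def test_single_doubly_censored_pair_reduces_to_region_logprob(self):
        th = BvnParams(0, 0, 1, 1, 0.0)
        pairs = (
            CensoredPair(x_status=CensorStatus.LEFT, x_limit=0.0,
                         y_status=CensorStatus.LEFT, y_lower=0.0),
            obs(1.0, 1.0),
        )
        part = partition_sample(PairedSample(pairs))
        ll = loglik_single(th, part, 0.0, 0.0)
        # subtract the observed pair's density: the censored term is log(1/4)
        ll_obs = math.log(bvn_pdf(1.0, 1.0, th))
        assert ll.value - ll_obs == pytest.approx(math.log(0.25), abs=1e-10)

    def test_fixture_terms_match_quadrature_oracle(self, single_fixture, theta_std):
        """Every censored term of the fixed-limit likelihood equals adaptive
        quadrature of the bivariate density over the censored region."""
        part = partition_sample(single_fixture)
        ll = loglik_single(theta_std, part, CX, CY).value
        oracle = 0.0
        for p in part.blocks["11"]:
            oracle += math.log(bvn_pdf(p.x_value, p.y_value, theta_std))
        for p in part.blocks["01"]:
            oracle += math.log(
                halfline_density_quadrature(theta_std, p.y_value, True, CX)
            )
        for p in part.blocks["10"]:
            oracle += math.log(
                halfline_density_quadrature(theta_std, p.x_value, False, CY)
            )
        oracle += part.count("00") * math.log(
            rect_prob_quadrature(theta_std, CX, -math.inf, CY)
        )
        assert ll == pytest.approx(oracle, rel=1e-6)

    def test_boundary_theta_signals_not_crashes(self, single_fixture):
        th = BvnParams(0.0, 0.0, 1e-8, 1e-8, 0.0)
        part = partition_sample(single_fixture)
        value = loglik_single(th, part, CX, CY).value
        assert value == -math.inf or math.isfinite(value)


class TestLoglikMulti:
    def test_reduces_to_single_with_constant_limits(self, single_fixture, theta_std):
        part = partition_sample(single_fixture)
        as_multi = PairedSample(single_fixture.pairs, scenario=Scenario.MULTI)
        ll_multi = loglik_multi(theta_std, partition_sample(as_multi))
        ll_single = loglik_single(theta_std, part, CX, CY)
        assert ll_multi.value == pytest.approx(ll_single.value, abs=1e-10)

    def test_interval_pair_closed_form(self):
        """x observed, y in [-0.1, 0.4]: the term is phi(x) (Phi(c2) - Phi(c1))
        of the conditional, hand-computed from the conditional parameters."""
        from scipy.stats import norm

        th = BvnParams(0, 0, 1, 1, 0.5)
        x = 0.3
        pairs = (
            obs(1.0, 1.0),
            obs(-1.0, -1.0),
            CensoredPair(x_value=x, y_status=CensorStatus.INTERVAL, y_lower=-0.1, y_upper=0.4),
        )
        part = partition_sample(PairedSample(pairs, scenario=Scenario.MULTI))
        ll = loglik_multi(th, part).value
        base = sum(math.log(bvn_pdf(a, b, th)) for a, b in [(1, 1), (-1, -1)])
        mu_c = 0.5 * x
        sd_c = math.sqrt(1 - 0.25)
        term = math.log(norm.pdf(x)) + math.log(
            norm.cdf((0.4 - mu_c) / sd_c) - norm.cdf((-0.1 - mu_c) / sd_c)
        )
        assert ll - base == pytest.approx(term, abs=1e-10)

    def test_left_plus_interval_pair_matches_2d_quadrature(self, theta_std):
        pairs = (
            obs(1.0, 1.0),
            obs(-1.0, -1.0),
            CensoredPair(
                x_status=CensorStatus.LEFT, x_limit=0.0,
                y_status=CensorStatus.INTERVAL, y_lower=0.0, y_upper=1.0,
            ),
        )
        part = partition_sample(PairedSample(pairs, scenario=Scenario.MULTI))
        ll = loglik_multi(theta_std, part).value
        base = sum(math.log(bvn_pdf(a, b, theta_std)) for a, b in [(1, 1), (-1, -1)])
        oracle = rect_prob_quadrature(theta_std, 0.0, 0.0, 1.0)
        assert ll - base == pytest.approx(math.log(oracle), rel=1e-6)

    def test_fixture_terms_match_quadrature_oracle(self, multi_fixture, theta_std):
        """Per-observation-limit likelihood, term by term against quadrature."""
        part = partition_sample(multi_fixture)
        ll = loglik_multi(theta_std, part).value
        oracle = 0.0
        for p in part.blocks["11"]:
            oracle += math.log(bvn_pdf(p.x_value, p.y_value, theta_std))
        for p in part.blocks["01"]:
            oracle += math.log(
                halfline_density_quadrature(theta_std, p.y_value, True, p.x_limit)
            )
        for p in part.blocks["10"]:
            oracle += math.log(
                halfline_density_quadrature(theta_std, p.x_value, False, p.y_lower)
            )
        for p in part.blocks["00"]:
            oracle += math.log(
                rect_prob_quadrature(theta_std, p.x_limit, -math.inf, p.y_lower)
            )
        for p in part.blocks["12"]:
            oracle += math.log(
                halfline_density_quadrature(
                    theta_std, p.x_value, False, p.y_lower, p.y_upper
                )
            )
        for p in part.blocks["02"]:
            oracle += math.log(
                rect_prob_quadrature(theta_std, p.x_limit, p.y_lower, p.y_upper)
            )
        assert ll == pytest.approx(oracle, rel=1e-6)


class TestInvariances:
    @settings(
        max_examples=20,
        derandomize=True,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(shift=st.floats(-5, 5))
    def test_translation_invariance(self, single_fixture, theta_std, shift):
        """Shifting all values, limits and both means leaves loglik unchanged."""

        def shift_pair(p: CensoredPair) -> CensoredPair:
            def mv(v):
                return None if v is None else v + shift

            return CensoredPair(
                x_value=mv(p.x_value), x_status=p.x_status, x_limit=mv(p.x_limit),
                y_value=mv(p.y_value), y_status=p.y_status,
                y_lower=mv(p.y_lower), y_upper=mv(p.y_upper),
            )

        shifted = PairedSample(tuple(shift_pair(p) for p in single_fixture.pairs))
        th2 = BvnParams(theta_std.mu_x + shift, theta_std.mu_y + shift,
                        theta_std.var_x, theta_std.var_y, theta_std.rho)
        ll0 = loglik_single(theta_std, partition_sample(single_fixture), CX, CY).value
        ll1 = loglik_single(th2, partition_sample(shifted), CX + shift, CY + shift).value
        assert ll1 == pytest.approx(ll0, abs=1e-8)

    def test_xy_swap_invariance(self, single_fixture):
        """Swapping the roles of X and Y (data and parameters) preserves loglik."""
        th = BvnParams(0.1, -0.2, 1.3, 0.8, 0.7)

        def swap_pair(p: CensoredPair) -> CensoredPair:
            return CensoredPair(
                x_value=p.y_value,
                x_status=p.y_status,
                x_limit=p.y_lower,
                y_value=p.x_value,
                y_status=p.x_status,
                y_lower=p.x_limit,
            )

        swapped = PairedSample(tuple(swap_pair(p) for p in single_fixture.pairs))
        th_swap = BvnParams(th.mu_y, th.mu_x, th.var_y, th.var_x, th.rho)
        ll0 = loglik_single(th, partition_sample(single_fixture), CX, CY).value
        ll1 = loglik_single(th_swap, partition_sample(swapped), CY, CX).value
        assert ll1 == pytest.approx(ll0, abs=1e-9)

    def test_dispatch_by_scenario(self, single_fixture, multi_fixture, theta_std):
        assert loglik(theta_std, partition_sample(single_fixture)).value == pytest.approx(
            loglik_single(theta_std, partition_sample(single_fixture), CX, CY).value
        )
        assert math.isfinite(loglik(theta_std, partition_sample(multi_fixture)).value)
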