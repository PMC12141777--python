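"""Shared fixtures: fixed censored samples spanning every likelihood category,
and quadrature helpers used as independent oracles for the censored terms."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate

from censba import BvnParams, CensoredPair, CensorStatus, PairedSample, Scenario


@pytest.fixture
def theta_std() -> BvnParams:
    """Standard margins with strong correlation, the study's central case."""
    return BvnParams(mu_x=0.0, mu_y=0.0, var_x=1.0, var_y=1.0, rho=0.9)


def obs(x: float, y: float) -> CensoredPair:
    return CensoredPair(x_value=x, y_value=y)


def xcens(cx: float, y: float) -> CensoredPair:
    return CensoredPair(x_status=CensorStatus.LEFT, x_limit=cx, y_value=y)


def ycens(x: float, cy: float) -> CensoredPair:
    return CensoredPair(x_value=x, y_status=CensorStatus.LEFT, y_lower=cy)


def bothcens(cx: float, cy: float) -> CensoredPair:
    return CensoredPair(
        x_status=CensorStatus.LEFT, x_limit=cx, y_status=CensorStatus.LEFT, y_lower=cy
    )


def yint(x: float, lo: float, hi: float) -> CensoredPair:
    return CensoredPair(x_value=x, y_status=CensorStatus.INTERVAL, y_lower=lo, y_upper=hi)


def xcens_yint(cx: float, lo: float, hi: float) -> CensoredPair:
    return CensoredPair(
        x_status=CensorStatus.LEFT, x_limit=cx,
        y_status=CensorStatus.INTERVAL, y_lower=lo, y_upper=hi,
    )


#: fixed single-limit censoring thresholds of the 12-pair fixture
CX, CY = -0.8, -0.5


@pytest.fixture
def single_fixture() -> PairedSample:
    """12 fixed pairs spanning all four fixed-limit categories (5/3/3/1)."""
    pairs = (
        obs(0.2, 0.1),
        obs(-0.3, -0.2),
        obs(1.4, 1.1),
        obs(0.6, 0.9),
        obs(-0.5, -0.1),
        xcens(CX, -0.4),
        xcens(CX, 0.3),
        xcens(CX, -0.3),
        ycens(-0.2, CY),
        ycens(0.1, CY),
        ycens(-0.6, CY),
        bothcens(CX, CY),
    )
    return PairedSample(pairs, scenario=Scenario.SINGLE)


@pytest.fixture
def multi_fixture() -> PairedSample:
    """12 fixed pairs spanning all six per-observation-limit categories."""
    pairs = (
        obs(0.2, 0.1),
        obs(-0.3, -0.2),
        obs(1.4, 1.1),
        xcens(-0.8, -0.4),
        xcens(-1.1, 0.3),
        ycens(-0.2, -0.5),
        ycens(0.1, -0.9),
        bothcens(-0.8, -0.5),
        bothcens(-1.2, -0.7),
        yint(0.3, -0.1, 0.4),
        yint(-0.4, -0.6, -0.2),
        xcens_yint(-0.9, -0.5, 0.1),
    )
    return PairedSample(pairs, scenario=Scenario.MULTI)


def bvn_pdf(x: float, y: float, th: BvnParams) -> float:
    """Bivariate normal density, written out for oracle independence."""
    zx = (x - th.mu_x) / th.sd_x
    zy = (y - th.mu_y) / th.sd_y
    q = (zx**2 - 2 * th.rho * zx * zy + zy**2) / (1 - th.rho**2)
    norm = 2 * math.pi * th.sd_x * th.sd_y * math.sqrt(1 - th.rho**2)
    return math.exp(-0.5 * q) / norm


def rect_prob_quadrature(
    th: BvnParams, x_upper: float, y_lower: float, y_upper: float
) -> float:
    """P(X <= x_upper, y_lower <= Y <= y_upper) by 2-D adaptive quadrature."""
    x_lo = th.mu_x - 9 * th.sd_x
    x_hi = min(x_upper, th.mu_x + 9 * th.sd_x)
    y_lo = max(y_lower, th.mu_y - 9 * th.sd_y)
    y_hi = min(y_upper, th.mu_y + 9 * th.sd_y)
    val, _ = integrate.dblquad(
        lambda y, x: bvn_pdf(x, y, th), x_lo, x_hi, y_lo, y_hi, epsabs=1e-12, epsrel=1e-10
    )
    return val


def halfline_density_quadrature(
    th: BvnParams, observed_value: float, censored_is_x: bool, limit: float,
    limit_upper: float | None = None,
) -> float:
    """Density of the observed member integrated over the censored range.

    With ``limit_upper`` set, integrates over [limit, limit_upper] (the
    interval-censored contribution); otherwise over (-inf, limit].
    """
    if censored_is_x:
        f = lambda t: bvn_pdf(t, observed_value, th)
        lo = limit - 9 * th.sd_x if limit_upper is None else limit
    else:
        f = lambda t: bvn_pdf(observed_value, t, th)
        lo = limit - 9 * th.sd_y if limit_upper is None else limit
    hi = limit if limit_upper is None else limit_upper
    val, _ = integrate.quad(f, lo, hi, epsabs=1e-13, epsrel=1e-10)
    return val
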