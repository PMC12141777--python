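"""Censored bivariate normal log-likelihoods.

The sample is partitioned into category blocks by censoring pattern.  Fully
observed pairs contribute the bivariate density (factored as f(y|x) f(x));
pairs with one censored member contribute the observed marginal density times
the normal CDF of the standardized conditional bound; doubly censored pairs
contribute the probability mass of their censoring rectangle.

Rectangle probabilities are evaluated through the bivariate normal CDF,
``P = Phi2(a, b2; rho) - Phi2(a, b1; rho)`` with standardized bounds, which
is algebraically identical to the one-dimensional integral of the marginal
density times the conditional CDF over the censored range (the quadrature
route is kept as an independent oracle in the test suite).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import multivariate_normal

from .datamodel import (
    BvnParams,
    CensorStatus,
    ConditionalParams,
    PartitionedSample,
    Scenario,
)

#: correlations are clamped to +/-(1 - RHO_EPS) so boundary evaluations during
#: optimization signal a poor fit instead of crashing
RHO_EPS = 1e-9

_LOG_2PI = math.log(2.0 * math.pi)


class Direction(str, Enum):
    X_GIVEN_Y = "x_given_y"
    Y_GIVEN_X = "y_given_x"


class DegenerateRegionError(ValueError):
    """The censoring region carries (numerically) no probability mass."""


@dataclass(frozen=True)
class LogLikValue:
    value: float
    n_terms: int


def conditional_params(
    theta: BvnParams, given_value: float, direction: Direction
) -> ConditionalParams:
    """Conditional normal parameters of one pair member given the other.

    ``mean = mu_t + rho * (sd_t / sd_g) * (given - mu_g)`` and
    ``var = var_t * (1 - rho^2)`` where t is the target variable and g the
    conditioning one.
    """
    if direction is Direction.X_GIVEN_Y:
        mu_t, sd_t, var_t = theta.mu_x, theta.sd_x, theta.var_x
        mu_g, sd_g = theta.mu_y, theta.sd_y
    else:
        mu_t, sd_t, var_t = theta.mu_y, theta.sd_y, theta.var_y
        mu_g, sd_g = theta.mu_x, theta.sd_x
    mean = mu_t + theta.rho * (sd_t / sd_g) * (given_value - mu_g)
    var = var_t * (1.0 - theta.rho**2)
    return ConditionalParams(mean=mean, var=var)


def _clamped_rho(rho: float) -> float:
    return max(-1.0 + RHO_EPS, min(1.0 - RHO_EPS, rho))


def _phi2(a: float, b: float, rho: float) -> float:
    """Standard bivariate normal CDF P(Z1 <= a, Z2 <= b) with correlation rho."""
    if a == -math.inf or b == -math.inf:
        return 0.0
    if a == math.inf and b == math.inf:
        return 1.0
    if a == math.inf:
        return float(ndtr(b))
    if b == math.inf:
        return float(ndtr(a))
    rho = _clamped_rho(rho)
    cov = [[1.0, rho], [rho, 1.0]]
    return float(multivariate_normal(mean=[0.0, 0.0], cov=cov).cdf([a, b]))


def censored_region_logprob(
    theta: BvnParams,
    x_upper: float,
    y_lower: float = -math.inf,
    y_upper: float = math.inf,
) -> float:
    """log P(X <= x_upper, y_lower <= Y <= y_upper) under the latent model.

    Raises :class:`DegenerateRegionError` when the region probability
    underflows (below 1e-300), which happens for zero-measure intervals or
    censoring limits many standard deviations into the tail.
    """
    if y_lower > y_upper:
        raise ValueError("y_lower must not exceed y_upper")
    a = (x_upper - theta.mu_x) / theta.sd_x if math.isfinite(x_upper) else x_upper
    b1 = (y_lower - theta.mu_y) / theta.sd_y if math.isfinite(y_lower) else y_lower
    b2 = (y_upper - theta.mu_y) / theta.sd_y if math.isfinite(y_upper) else y_upper
    p = _phi2(a, b2, theta.rho)
    if b1 != -math.inf:
        p -= _phi2(a, b1, theta.rho)
    if not p > 1e-300:
        raise DegenerateRegionError(
            f"censoring region x<={x_upper}, {y_lower}<=y<={y_upper} has no mass"
        )
    return math.log(p)


def _normal_logpdf(values: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + math.log(var)) - 0.5 * (values - mean) ** 2 / var


def _block11(theta: BvnParams, xs: np.ndarray, ys: np.ndarray) -> float:
    """Joint log-density of fully observed pairs via f(x) f(y|x)."""
    var_cond = theta.var_y * (1.0 - theta.rho**2)
    mu_cond = theta.mu_y + theta.rho * (theta.sd_y / theta.sd_x) * (xs - theta.mu_x)
    ll = _normal_logpdf(xs, theta.mu_x, theta.var_x)
    ll = ll + (-0.5 * (_LOG_2PI + math.log(var_cond)) - 0.5 * (ys - mu_cond) ** 2 / var_cond)
    return float(np.sum(ll))


def _block_one_censored(
    theta: BvnParams,
    observed: np.ndarray,
    limits: np.ndarray,
    censored_is_x: bool,
) -> float:
    """Marginal density of the observed member plus log Phi of the conditional bound."""
    if censored_is_x:
        mu_obs, var_obs = theta.mu_y, theta.var_y
        mu_c, sd_c, sd_obs = theta.mu_x, theta.sd_x, theta.sd_y
    else:
        mu_obs, var_obs = theta.mu_x, theta.var_x
        mu_c, sd_c, sd_obs = theta.mu_y, theta.sd_y, theta.sd_x
    sd_cond = sd_c * math.sqrt(1.0 - theta.rho**2)
    mu_cond = mu_c + theta.rho * (sd_c / sd_obs) * (observed - mu_obs)
    ll = _normal_logpdf(observed, mu_obs, var_obs)
    ll = ll + log_ndtr((limits - mu_cond) / sd_cond)
    return float(np.sum(ll))


def _block_interval(
    theta: BvnParams, xs: np.ndarray, lowers: np.ndarray, uppers: np.ndarray
) -> float:
    """x observed, y interval-censored: f(x) * [Phi(c2) - Phi(c1)] of the conditional."""
    sd_cond = theta.sd_y * math.sqrt(1.0 - theta.rho**2)
    mu_cond = theta.mu_y + theta.rho * (theta.sd_y / theta.sd_x) * (xs - theta.mu_x)
    p = ndtr((uppers - mu_cond) / sd_cond) - ndtr((lowers - mu_cond) / sd_cond)
    if np.any(p <= 0.0):
        return -math.inf
    return float(np.sum(_normal_logpdf(xs, theta.mu_x, theta.var_x) + np.log(p)))


def _clamp_theta(theta: BvnParams) -> BvnParams:
    rho = _clamped_rho(theta.rho)
    if rho != theta.rho:
        theta = BvnParams(theta.mu_x, theta.mu_y, theta.var_x, theta.var_y, rho)
    return theta


def loglik_single(
    theta: BvnParams, part: PartitionedSample, Cx: float | None, Cy: float | None
) -> LogLikValue:
    """Log-likelihood for the fixed-limit scenario.

    ``Cx`` / ``Cy`` may be None when the respective variable has no censored
    record.  A non-finite result (e.g. from a boundary theta) is returned as
    ``-inf`` rather than raised, so optimizers can treat it as a rejection.
    """
    if part.count("12") or part.count("02"):
        raise ValueError("interval-censored records require loglik_multi")
    theta = _clamp_theta(theta)
    total = 0.0
    b11 = part.blocks["11"]
    if b11:
        xs = np.array([p.x_value for p in b11])
        ys = np.array([p.y_value for p in b11])
        total += _block11(theta, xs, ys)
    b01 = part.blocks["01"]
    if b01:
        ys = np.array([p.y_value for p in b01])
        total += _block_one_censored(theta, ys, np.full(len(b01), Cx), censored_is_x=True)
    b10 = part.blocks["10"]
    if b10:
        xs = np.array([p.x_value for p in b10])
        total += _block_one_censored(theta, xs, np.full(len(b10), Cy), censored_is_x=False)
    n00 = part.count("00")
    if n00:
        try:
            total += n00 * censored_region_logprob(theta, Cx, -math.inf, Cy)
        except DegenerateRegionError:
            total = -math.inf
    if not math.isfinite(total):
        total = -math.inf
    return LogLikValue(value=total, n_terms=part.n)


def loglik_multi(theta: BvnParams, part: PartitionedSample) -> LogLikValue:
    """Log-likelihood with per-observation left and interval censoring limits.

    Reduces to :func:`loglik_single` when all limits coincide and no
    interval-censored record is present.
    """
    theta = _clamp_theta(theta)
    total = 0.0
    b11 = part.blocks["11"]
    if b11:
        xs = np.array([p.x_value for p in b11])
        ys = np.array([p.y_value for p in b11])
        total += _block11(theta, xs, ys)
    b01 = part.blocks["01"]
    if b01:
        ys = np.array([p.y_value for p in b01])
        lims = np.array([p.x_limit for p in b01])
        total += _block_one_censored(theta, ys, lims, censored_is_x=True)
    b10 = part.blocks["10"]
    if b10:
        xs = np.array([p.x_value for p in b10])
        lims = np.array([p.y_lower for p in b10])
        total += _block_one_censored(theta, xs, lims, censored_is_x=False)
    b12 = part.blocks["12"]
    if b12:
        xs = np.array([p.x_value for p in b12])
        lo = np.array([p.y_lower for p in b12])
        hi = np.array([p.y_upper for p in b12])
        total += _block_interval(theta, xs, lo, hi)
    try:
        for pair in part.blocks["00"]:
            total += censored_region_logprob(theta, pair.x_limit, -math.inf, pair.y_lower)
        for pair in part.blocks["02"]:
            total += censored_region_logprob(theta, pair.x_limit, pair.y_lower, pair.y_upper)
    except DegenerateRegionError:
        total = -math.inf
    if not math.isfinite(total):
        total = -math.inf
    return LogLikValue(value=total, n_terms=part.n)


def loglik(theta: BvnParams, part: PartitionedSample) -> LogLikValue:
    """Dispatch on the partition's scenario."""
    if part.scenario is Scenario.SINGLE:
        from .datamodel import single_limits

        cx, cy = single_limits(part)
        return loglik_single(theta, part, cx, cy)
    return loglik_multi(theta, part)
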