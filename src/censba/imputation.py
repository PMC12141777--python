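"""Multiple imputation of censored pairs from the fitted latent model.

Pairs with exactly one censored member are imputed by two-step inverse-CDF
sampling from the conditional normal given the observed member, truncated to
the censoring region: a uniform variate is drawn on the CDF-image of the
region and pushed through the quantile function.  Doubly censored pairs are
drawn from the bivariate normal restricted to their censoring rectangle —
by rejection from the unrestricted distribution while the rectangle holds
enough mass, and by an exact conditional-chain construction (numerical
inversion of the rectangle's y-marginal CDF, then the truncated conditional
for x) when the acceptance rate would be poor.

All samplers are deterministic given their seed; every draw respects the
censoring region with closed bounds.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri

from .datamodel import (
    BvnParams,
    CensorStatus,
    ImputedPoints,
    ImputedSample,
    PairedSample,
    validate_sample,
)
from .likelihood import (
    DegenerateRegionError,
    Direction,
    censored_region_logprob,
    conditional_params,
)

SeedLike = int | np.random.SeedSequence | np.random.Generator


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_normal_draws(
    mean: float,
    sd: float,
    lower: float,
    upper: float,
    m: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF draws from N(mean, sd^2) restricted to [lower, upper]."""
    if lower == upper:
        return np.full(m, lower)
    f_lo = float(ndtr((lower - mean) / sd)) if math.isfinite(lower) else 0.0
    f_hi = float(ndtr((upper - mean) / sd)) if math.isfinite(upper) else 1.0
    if not f_hi - f_lo > 0.0:
        raise DegenerateRegionError(
            f"conditional mass in [{lower}, {upper}] vanishes (CDF range {f_lo}..{f_hi})"
        )
    u = rng.uniform(f_lo, f_hi, size=m)
    draws = mean + sd * ndtri(u)
    return np.clip(draws, lower, upper)


def impute_left_conditional(
    obs_value: float,
    limit: float,
    theta: BvnParams,
    direction: Direction,
    m: int,
    seed: SeedLike,
    pair_index: int = 0,
) -> ImputedPoints:
    """Impute a left-censored member given the observed partner.

    ``direction=X_GIVEN_Y`` imputes x below ``limit`` given y = obs_value,
    and vice versa.  Draws come from the conditional normal truncated above
    at the limit via the two-step uniform/quantile construction.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    cond = conditional_params(theta, obs_value, direction)
    rng = _rng(seed)
    draws = _truncated_normal_draws(cond.mean, cond.sd, -math.inf, limit, m, rng)
    if direction is Direction.X_GIVEN_Y:
        pairs = tuple((float(x), float(obs_value)) for x in draws)
        category = "01"
    else:
        pairs = tuple((float(obs_value), float(y)) for y in draws)
        category = "10"
    return ImputedPoints(pair_index=pair_index, category=category, draws=pairs)


def impute_interval_conditional(
    obs_x: float,
    y_lower: float,
    y_upper: float,
    theta: BvnParams,
    m: int,
    seed: SeedLike,
    pair_index: int = 0,
) -> ImputedPoints:
    """Impute an interval-censored y given observed x.

    The uniform variate is drawn between the conditional CDF values at the
    interval endpoints and pushed through the conditional quantile function.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    cond = conditional_params(theta, obs_x, Direction.Y_GIVEN_X)
    rng = _rng(seed)
    draws = _truncated_normal_draws(cond.mean, cond.sd, y_lower, y_upper, m, rng)
    return ImputedPoints(
        pair_index=pair_index,
        category="12",
        draws=tuple((float(obs_x), float(y)) for y in draws),
    )


#: below this rectangle probability the rejection sampler gives way to the
#: conditional-chain sampler (deep censoring under bootstrap-perturbed theta)
REJECTION_MIN_PROB = 0.01


def sample_truncated_bvn(
    theta: BvnParams,
    x_upper: float,
    y_lower: float,
    y_upper: float,
    m: int,
    seed: SeedLike,
) -> list[tuple[float, float]]:
    """Draws from the bivariate normal restricted to (-inf, x_upper] x [y_lower, y_upper]."""
    if m < 1:
        raise ValueError("m must be at least 1")
    try:
        logp = censored_region_logprob(theta, x_upper, y_lower, y_upper)
    except DegenerateRegionError:
        logp = -math.inf
    p_region = math.exp(logp)
    if p_region < 1e-12:
        raise DegenerateRegionError(
            f"region x<={x_upper}, {y_lower}<=y<={y_upper} has probability {p_region:.3g}"
        )
    rng = _rng(seed)
    if p_region >= REJECTION_MIN_PROB:
        return _rejection_sample(theta, x_upper, y_lower, y_upper, m, rng)
    return _chain_sample(theta, x_upper, y_lower, y_upper, p_region, m, rng)


def _rejection_sample(theta, x_upper, y_lower, y_upper, m, rng):
    cov = [
        [theta.var_x, theta.rho * theta.sd_x * theta.sd_y],
        [theta.rho * theta.sd_x * theta.sd_y, theta.var_y],
    ]
    mean = [theta.mu_x, theta.mu_y]
    out: list[tuple[float, float]] = []
    while len(out) < m:
        batch = rng.multivariate_normal(mean, cov, size=max(64, 2 * (m - len(out))))
        ok = (batch[:, 0] <= x_upper) & (batch[:, 1] >= y_lower) & (batch[:, 1] <= y_upper)
        for x, y in batch[ok]:
            out.append((float(x), float(y)))
            if len(out) == m:
                break
    return out


def _chain_sample(theta, x_upper, y_lower, y_upper, p_region, m, rng):
    """Exact draws: invert the rectangle's y-marginal CDF, then x | y truncated."""

    def marginal_cdf(y: float) -> float:
        # P(X <= x_upper, y_lower <= Y <= y) / p_region
        if y <= y_lower:
            return 0.0
        try:
            return math.exp(censored_region_logprob(theta, x_upper, y_lower, y)) / p_region
        except DegenerateRegionError:
            return 0.0

    lo = y_lower if math.isfinite(y_lower) else theta.mu_y - 40.0 * theta.sd_y
    hi = y_upper if math.isfinite(y_upper) else theta.mu_y + 40.0 * theta.sd_y
    out: list[tuple[float, float]] = []
    for u in rng.uniform(0.0, 1.0, size=m):
        y = brentq(lambda t: marginal_cdf(t) - u, lo, hi, xtol=1e-12)
        cond = conditional_params(theta, y, Direction.X_GIVEN_Y)
        x = _truncated_normal_draws(cond.mean, cond.sd, -math.inf, x_upper, 1, rng)[0]
        out.append((float(x), float(max(min(y, hi), lo))))
    return out


def impute_sample(
    sample: PairedSample, theta_hat: BvnParams, m: int = 20, seed: SeedLike = 0
) -> ImputedSample:
    """Multiply impute every censored pair and return plotting coordinates.

    Fully observed pairs become single (mean, diff) points; each censored
    pair contributes m imputed points drawn from its conditional or truncated
    bivariate distribution under ``theta_hat`` (in practice the combined
    bootstrap estimate).  Per-pair substreams keep the result reproducible
    and independent of processing order.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    sample = validate_sample(sample)
    root = seed if isinstance(seed, (int, np.integer)) else 0
    observed: list[tuple[float, float]] = []
    imputed: list[ImputedPoints] = []
    for i, pair in enumerate(sample.pairs):
        cat = pair.category
        if cat == "11":
            observed.append((0.5 * (pair.x_value + pair.y_value), pair.y_value - pair.x_value))
            continue
        sub = np.random.SeedSequence(entropy=root, spawn_key=(i,))
        if cat == "01":
            ip = impute_left_conditional(
                pair.y_value, pair.x_limit, theta_hat, Direction.X_GIVEN_Y, m, sub, i
            )
        elif cat == "10":
            ip = impute_left_conditional(
                pair.x_value, pair.y_lower, theta_hat, Direction.Y_GIVEN_X, m, sub, i
            )
        elif cat == "12":
            ip = impute_interval_conditional(
                pair.x_value, pair.y_lower, pair.y_upper, theta_hat, m, sub, i
            )
        elif cat == "00":
            draws = sample_truncated_bvn(
                theta_hat, pair.x_limit, -math.inf, pair.y_lower, m, np.random.default_rng(sub)
            )
            ip = ImputedPoints(pair_index=i, category="00", draws=tuple(draws))
        else:  # "02"
            draws = sample_truncated_bvn(
                theta_hat, pair.x_limit, pair.y_lower, pair.y_upper, m, np.random.default_rng(sub)
            )
            ip = ImputedPoints(pair_index=i, category="02", draws=tuple(draws))
        imputed.append(ip)
    return ImputedSample(observed_points=tuple(observed), imputed=tuple(imputed), m=m)
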