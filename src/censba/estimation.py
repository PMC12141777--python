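"""Maximum-likelihood fitting and reference-line estimators.

Three routes to the bias line and limits of agreement are provided:

* model-based: ``d = mu_y - mu_x``, ``s = sqrt(var_x + var_y - 2 rho sd_x sd_y)``
  evaluated at a (censored-)ML estimate of the latent bivariate normal;
* empirical: the classical mean difference and n-1 standard deviation of the
  observed differences (used by the complete-case and naive comparators);
* Rubin-pooled: classical lines per imputed dataset combined across
  imputations.

The ML variance estimates use divisor n (likelihood-consistent); the
empirical standard deviation uses divisor n-1.  The two conventions are kept
deliberately distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .datamodel import (
    BvnParams,
    CensorStatus,
    PairedSample,
    ReferenceLines,
    Scale,
    partition_sample,
    substitute_pair,
    validate_sample,
)
from .likelihood import RHO_EPS, loglik


class IdentifiabilityError(ValueError):
    """The sample has too few fully observed pairs to identify the model."""


@dataclass(frozen=True)
class FitResult:
    params: BvnParams
    loglik: float
    converged: bool
    n_evals: int
    start_params: BvnParams


def z_quantile(coverage: float = 0.95) -> float:
    """Standard-normal quantile for two-sided limits (0.975 quantile for 95%)."""
    return float(norm.ppf(1.0 - (1.0 - coverage) / 2.0))


def reference_lines_from_theta(theta: BvnParams, coverage: float = 0.95) -> ReferenceLines:
    """Closed-form reference lines implied by the latent bivariate normal."""
    bias = theta.mu_y - theta.mu_x
    var_diff = theta.var_x + theta.var_y - 2.0 * theta.rho * theta.sd_x * theta.sd_y
    sd = math.sqrt(max(var_diff, 0.0))
    return ReferenceLines(bias=bias, sd_diff=sd, z_quantile=z_quantile(coverage))


def reference_lines_empirical(diffs, coverage: float = 0.95) -> ReferenceLines:
    """Classical mean-difference lines: mean, n-1 SD, mean +/- z * SD."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("sd undefined: need at least 2 differences")
    return ReferenceLines(
        bias=float(np.mean(d)), sd_diff=float(np.std(d, ddof=1)), z_quantile=z_quantile(coverage)
    )


def complete_case_lines(sample: PairedSample, coverage: float = 0.95) -> ReferenceLines:
    """Empirical lines from the fully observed pairs only."""
    diffs = [
        p.y_value - p.x_value
        for p in sample.pairs
        if p.x_status is CensorStatus.OBSERVED and p.y_status is CensorStatus.OBSERVED
    ]
    if len(diffs) < 2:
        raise ValueError("complete-case analysis needs at least 2 fully observed pairs")
    return reference_lines_empirical(diffs, coverage)


def naive_substitute(sample: PairedSample, fraction: float = 0.5) -> PairedSample:
    """Replace censored members by a fixed fraction of their limit.

    The convention "half the limit of quantification" lives on the original
    measurement scale, so for log-scale (LOGNORMAL) data the substituted
    value is ``limit + log(fraction)``; interval-censored records get the
    interval midpoint.  All statuses become OBSERVED; order is preserved.
    """
    log_scale = sample.scale is Scale.LOGNORMAL
    offset = math.log(fraction) if log_scale else None
    new_pairs = []
    for pair in sample.pairs:
        x_sub = y_sub = None
        if pair.x_status is CensorStatus.LEFT:
            x_sub = pair.x_limit + offset if log_scale else fraction * pair.x_limit
        if pair.y_status is CensorStatus.LEFT:
            y_sub = pair.y_lower + offset if log_scale else fraction * pair.y_lower
        elif pair.y_status is CensorStatus.INTERVAL:
            y_sub = 0.5 * (pair.y_lower + pair.y_upper)
        new_pairs.append(substitute_pair(pair, x_sub, y_sub))
    return PairedSample(tuple(new_pairs), scenario=sample.scenario, scale=sample.scale)


def naive_lines(sample: PairedSample, fraction: float = 0.5, coverage: float = 0.95) -> ReferenceLines:
    """Empirical lines after naive substitution of all censored members."""
    completed = naive_substitute(sample, fraction)
    diffs = [p.y_value - p.x_value for p in completed.pairs]
    return reference_lines_empirical(diffs, coverage)


def rubin_combine(per_imputation_lines, n: int, coverage: float = 0.95) -> ReferenceLines:
    """Pool per-imputation reference lines with Rubin's rules.

    Point estimates are the means over imputations; the total variance of
    each estimate is W + (1 + 1/m) B with W the mean within-imputation
    variance (large-sample Bland-Altman formulas: var(d) = s^2/n for the
    bias; s^2 (1/n + z^2 / (2(n-1))) for each limit) and B the
    between-imputation variance.  CIs use a normal approximation.
    """
    lines = list(per_imputation_lines)
    m = len(lines)
    if m < 2:
        raise ValueError("Rubin pooling needs at least 2 imputations")
    z = lines[0].z_quantile
    biases = np.array([ln.bias for ln in lines])
    lowers = np.array([ln.lower for ln in lines])
    uppers = np.array([ln.upper for ln in lines])
    sds = np.array([ln.sd_diff for ln in lines])
    var_bias_w = sds**2 / n
    var_limit_w = sds**2 * (1.0 / n + z**2 / (2.0 * (n - 1)))
    zc = z_quantile(coverage)

    def pool(est: np.ndarray, within: np.ndarray) -> tuple[float, tuple[float, float]]:
        point = float(np.mean(est))
        b = float(np.var(est, ddof=1))
        t = float(np.mean(within)) + (1.0 + 1.0 / m) * b
        half = zc * math.sqrt(t)
        return point, (point - half, point + half)

    bias, ci_bias = pool(biases, var_bias_w)
    lower, ci_lower = pool(lowers, var_limit_w)
    upper, ci_upper = pool(uppers, var_limit_w)
    return ReferenceLines(
        bias=bias,
        sd_diff=float(np.mean(sds)),
        z_quantile=z,
        lower=lower,
        upper=upper,
        ci_bias=ci_bias,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
    )


# --- maximum likelihood -----------------------------------------------------


def _pack(theta: BvnParams) -> np.ndarray:
    """Map to the unconstrained space (mu_x, mu_y, log sd_x, log sd_y, atanh rho)."""
    return np.array(
        [
            theta.mu_x,
            theta.mu_y,
            0.5 * math.log(theta.var_x),
            0.5 * math.log(theta.var_y),
            math.atanh(max(-1 + 1e-12, min(1 - 1e-12, theta.rho))),
        ]
    )


def _unpack(z: np.ndarray) -> BvnParams:
    rho = math.tanh(z[4])
    rho = max(-1.0 + RHO_EPS, min(1.0 - RHO_EPS, rho))
    return BvnParams(
        mu_x=float(z[0]),
        mu_y=float(z[1]),
        var_x=float(math.exp(2.0 * z[2])),
        var_y=float(math.exp(2.0 * z[3])),
        rho=rho,
    )


def moment_params(sample: PairedSample) -> BvnParams:
    """Complete-data moment estimates (divisor n) of a fully observed sample."""
    xs = np.array([p.x_value for p in sample.pairs], dtype=float)
    ys = np.array([p.y_value for p in sample.pairs], dtype=float)
    var_x = float(np.var(xs))
    var_y = float(np.var(ys))
    cov = float(np.mean((xs - xs.mean()) * (ys - ys.mean())))
    rho = cov / math.sqrt(var_x * var_y) if var_x > 0 and var_y > 0 else 0.0
    rho = max(-1.0 + RHO_EPS, min(1.0 - RHO_EPS, rho))
    return BvnParams(
        mu_x=float(xs.mean()),
        mu_y=float(ys.mean()),
        var_x=max(var_x, 1e-12),
        var_y=max(var_y, 1e-12),
        rho=rho,
    )


def fit_mle(sample: PairedSample, validate: bool = True) -> FitResult:
    """Maximize the censored bivariate normal likelihood.

    The search runs on the unconstrained parameterization with Nelder-Mead
    and one restart from a perturbed start; the start point is the moment
    estimate of the naive-substituted sample (always defined and inside the
    domain).  At least 2 fully observed pairs are required.
    """
    if validate:
        sample = validate_sample(sample)
    part = partition_sample(sample)
    if part.count("11") < 2:
        raise IdentifiabilityError(
            f"need at least 2 fully observed pairs, got {part.count('11')}"
        )
    start = moment_params(naive_substitute(sample))
    z0 = _pack(start)

    def objective(z: np.ndarray) -> float:
        try:
            return -loglik(_unpack(z), part).value
        except (OverflowError, FloatingPointError):
            return math.inf

    opts = dict(xatol=1e-8, fatol=1e-10, maxiter=4000, maxfev=6000)
    res = minimize(objective, z0, method="Nelder-Mead", options=opts)
    n_evals = res.nfev
    # one restart from a deterministic perturbation of the first solution
    perturb = np.array([0.05, -0.05, 0.1, -0.1, 0.2])
    res2 = minimize(objective, res.x + perturb, method="Nelder-Mead", options=opts)
    n_evals += res2.nfev
    best = res2 if res2.fun < res.fun else res
    theta_hat = _unpack(best.x)
    return FitResult(
        params=theta_hat,
        loglik=-float(best.fun),
        converged=bool(res.success or res2.success),
        n_evals=int(n_evals),
        start_params=start,
    )
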