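"""Synthetic censored bivariate (log)normal samples and the estimator study.

The generator draws latent pairs from a bivariate normal on the analysis
(log) scale and censors them at fixed theoretical marginal quantiles, so a
nominal censoring proportion p yields a Binomial(n, p) censored count.  The
study engine compares complete-case analysis, naive half-limit substitution
and censored maximum likelihood against the closed-form reference lines of
the generating distribution, reporting bias and mean squared error per
method and quantity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .datamodel import (
    BvnParams,
    CensoredPair,
    CensorStatus,
    PairedSample,
    ReferenceLines,
    Scale,
    Scenario,
)
from .estimation import (
    IdentifiabilityError,
    complete_case_lines,
    fit_mle,
    naive_lines,
    reference_lines_from_theta,
)

METHODS = ("complete_case", "naive", "ml")
QUANTITIES = ("bias_line", "lower_limit", "upper_limit")

#: default latent parameters of the study: standard lognormal margins with
#: strong correlation, the regime in which method comparison is hardest
DEFAULT_THETA = BvnParams(mu_x=0.0, mu_y=0.0, var_x=1.0, var_y=1.0, rho=0.9)


@dataclass(frozen=True)
class SimScenario:
    """One cell of the study design.

    Censoring proportions are nominal marginal probabilities; limits are the
    corresponding theoretical quantiles of the latent margins, so achieved
    censored counts vary binomially around n * p.
    """

    n: int
    theta: BvnParams = DEFAULT_THETA
    p_cens_x: float = 0.0
    p_cens_y: float = 0.0
    p_interval_y: float = 0.0
    iterations: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_cens_x, self.p_cens_y, self.p_interval_y):
            if not 0.0 <= p < 1.0:
                raise ValueError("censoring proportions must lie in [0, 1)")
        if self.p_cens_y + self.p_interval_y >= 1.0:
            raise ValueError("total y censoring must stay below 1")

    @property
    def scenario_kind(self) -> Scenario:
        return Scenario.MULTI if self.p_interval_y > 0 else Scenario.SINGLE


@dataclass(frozen=True)
class BiasMseTable:
    """Bias and MSE per (method, quantity), with the generating truth attached."""

    table: pd.DataFrame  # index (method, quantity); columns bias, mse
    true_lines: ReferenceLines
    n_iterations: int
    n_failed: dict[str, int]
    n_redrawn: int
    warnings: tuple[str, ...] = field(default_factory=tuple)

    def cell(self, method: str, quantity: str) -> tuple[float, float]:
        row = self.table.loc[(method, quantity)]
        return float(row["bias"]), float(row["mse"])


def generate_censored_sample(scenario: SimScenario, iteration: int) -> PairedSample:
    """Draw one censored sample, deterministic given (scenario.seed, iteration).

    Latent pairs come from the bivariate normal ``scenario.theta``;
    x values below the p_cens_x quantile are marked left-censored at that
    quantile, and similarly for y.  When ``p_interval_y > 0``, y values
    between the p_cens_y and (p_cens_y + p_interval_y) quantiles are marked
    interval-censored with those quantiles as bounds.
    """
    th = scenario.theta
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=scenario.seed, spawn_key=(iteration,))
    )
    cov = [
        [th.var_x, th.rho * th.sd_x * th.sd_y],
        [th.rho * th.sd_x * th.sd_y, th.var_y],
    ]
    latent = rng.multivariate_normal([th.mu_x, th.mu_y], cov, size=scenario.n)
    cx = th.mu_x + th.sd_x * ndtri(scenario.p_cens_x) if scenario.p_cens_x > 0 else None
    cy1 = th.mu_y + th.sd_y * ndtri(scenario.p_cens_y) if scenario.p_cens_y > 0 else None
    cy2 = (
        th.mu_y + th.sd_y * ndtri(scenario.p_cens_y + scenario.p_interval_y)
        if scenario.p_interval_y > 0
        else None
    )
    pairs = []
    for x, y in latent:
        if cx is not None and x <= cx:
            xv, xs, xl = None, CensorStatus.LEFT, cx
        else:
            xv, xs, xl = float(x), CensorStatus.OBSERVED, None
        if cy1 is not None and y <= cy1:
            yv, ys, ylo, yhi = None, CensorStatus.LEFT, cy1, None
        elif cy2 is not None and y <= cy2:
            yv, ys, ylo, yhi = None, CensorStatus.INTERVAL, cy1 if cy1 is not None else -math.inf, cy2
        else:
            yv, ys, ylo, yhi = float(y), CensorStatus.OBSERVED, None, None
        pairs.append(
            CensoredPair(
                x_value=xv, x_status=xs, x_limit=xl,
                y_value=yv, y_status=ys, y_lower=ylo, y_upper=yhi,
            )
        )
    return PairedSample(tuple(pairs), scenario=scenario.scenario_kind, scale=Scale.LOGNORMAL)


def _estimate(method: str, sample: PairedSample) -> ReferenceLines:
    if method == "complete_case":
        return complete_case_lines(sample)
    if method == "naive":
        return naive_lines(sample)
    if method == "ml":
        fit = fit_mle(sample, validate=False)
        if not fit.converged:
            raise IdentifiabilityError("ML fit did not converge")
        return reference_lines_from_theta(fit.params)
    raise ValueError(f"unknown method {method!r}")


def run_scenario(scenario: SimScenario, methods=METHODS) -> BiasMseTable:
    """Run one study cell: simulate, estimate with every method, score.

    Iterations where complete-case analysis would be undefined (< 2 complete
    pairs) are redrawn; iterations where any requested method fails are
    dropped for all methods (pairwise deletion) and counted.
    """
    truth = reference_lines_from_theta(scenario.theta)
    true_vals = {"bias_line": truth.bias, "lower_limit": truth.lower, "upper_limit": truth.upper}
    errors: dict[str, dict[str, list[float]]] = {
        m: {q: [] for q in QUANTITIES} for m in methods
    }
    n_failed = {m: 0 for m in methods}
    n_redrawn = 0
    draw = itertools.count()
    completed = 0
    while completed < scenario.iterations:
        sample = generate_censored_sample(scenario, next(draw))
        n_complete = sum(1 for p in sample.pairs if p.category == "11")
        if n_complete < 2:
            n_redrawn += 1
            continue
        est: dict[str, ReferenceLines] = {}
        failed = None
        for m in methods:
            try:
                est[m] = _estimate(m, sample)
            except (IdentifiabilityError, ValueError):
                failed = m
                break
        if failed is not None:
            n_failed[failed] += 1
            completed += 1  # counted against the budget, excluded pairwise
            continue
        for m in methods:
            lines = est[m]
            vals = {"bias_line": lines.bias, "lower_limit": lines.lower, "upper_limit": lines.upper}
            for q in QUANTITIES:
                errors[m][q].append(vals[q] - true_vals[q])
        completed += 1
    warnings = tuple(
        f"method {m}: {k} failed iterations (> 5%)"
        for m, k in n_failed.items()
        if k > 0.05 * scenario.iterations
    )
    rows = []
    for m in methods:
        for q in QUANTITIES:
            errs = np.array(errors[m][q])
            rows.append(
                {
                    "method": m,
                    "quantity": q,
                    "bias": float(errs.mean()) if errs.size else math.nan,
                    "mse": float(np.mean(errs**2)) if errs.size else math.nan,
                }
            )
    table = pd.DataFrame(rows).set_index(["method", "quantity"])
    n_used = len(next(iter(errors.values()))["bias_line"])
    return BiasMseTable(
        table=table,
        true_lines=truth,
        n_iterations=n_used,
        n_failed=n_failed,
        n_redrawn=n_redrawn,
        warnings=warnings,
    )


def run_simulation_study(scenarios, methods=METHODS) -> dict[SimScenario, BiasMseTable]:
    """Run several study cells and return one table per scenario."""
    return {sc: run_scenario(sc, methods) for sc in scenarios}


def paper_scale_grid(iterations: int = 2000, seed: int = 0) -> list[SimScenario]:
    """The full 15-cell design: n in {30, 50, 100} crossed with censoring
    proportions (x%, y%) in {(10,10), (10,20), (10,30), (10,40), (30,30)}."""
    cells = [(0.10, 0.10), (0.10, 0.20), (0.10, 0.30), (0.10, 0.40), (0.30, 0.30)]
    return [
        SimScenario(n=n, p_cens_x=px, p_cens_y=py, iterations=iterations, seed=seed)
        for n in (30, 50, 100)
        for px, py in cells
    ]


def results_to_frame(results: dict[SimScenario, BiasMseTable]) -> pd.DataFrame:
    """Long-format results: one row per scenario x method x quantity."""
    rows = []
    for sc, tab in results.items():
        for (m, q), row in tab.table.iterrows():
            rows.append(
                {
                    "n": sc.n,
                    "p_cens_x": sc.p_cens_x,
                    "p_cens_y": sc.p_cens_y,
                    "p_interval_y": sc.p_interval_y,
                    "iterations": tab.n_iterations,
                    "method": m,
                    "quantity": q,
                    "bias": row["bias"],
                    "mse": row["mse"],
                    "n_failed": tab.n_failed[m],
                }
            )
    return pd.DataFrame(rows)
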