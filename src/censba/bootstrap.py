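"""Pair-level bootstrap of the censored-model reference lines.

Resampling happens at the pair level so the x-y coupling (and any
per-observation limits) travel together.  Each resample is refit by maximum
likelihood; resamples that cannot be fit (too few complete pairs, failed
convergence) are discarded and redrawn.  Replicate estimates are combined by
their arithmetic mean, with percentile confidence intervals.

Randomness: one root seed spawns an independent stream per draw attempt, so
replicate k is the same regardless of how many earlier draws were discarded
elsewhere or how work is scheduled.
"""

from __future__ import annotations

import numpy as np

from .datamodel import BootstrapResult, BvnParams, PairedSample, ReferenceLines, validate_sample
from .estimation import IdentifiabilityError, fit_mle, reference_lines_from_theta


class BootstrapError(RuntimeError):
    """The redraw budget was exhausted before B converged replicates."""


def _resample(sample: PairedSample, rng: np.random.Generator) -> PairedSample:
    n = len(sample.pairs)
    idx = rng.integers(0, n, size=n)
    return PairedSample(
        tuple(sample.pairs[i] for i in idx), scenario=sample.scenario, scale=sample.scale
    )


def bootstrap_fit(
    sample: PairedSample,
    B: int,
    seed: int,
    max_redraws: int | None = None,
    coverage: float = 0.95,
) -> BootstrapResult:
    """Draw B pair-level resamples and refit the model in each.

    Returns the converged replicates (params and closed-form reference
    lines); ``n_failed`` counts discarded resamples.  Deterministic given
    ``seed``.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    sample = validate_sample(sample)
    if max_redraws is None:
        max_redraws = 10 * B
    replicates: list[tuple[BvnParams, ReferenceLines]] = []
    n_failed = 0
    attempt = 0
    while len(replicates) < B:
        if n_failed > max_redraws:
            raise BootstrapError(
                f"redraw budget exhausted: {n_failed} failed fits for {B} requested replicates"
            )
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(attempt,)))
        attempt += 1
        resample = _resample(sample, rng)
        try:
            fit = fit_mle(resample, validate=False)
        except IdentifiabilityError:
            n_failed += 1
            continue
        if not fit.converged:
            n_failed += 1
            continue
        replicates.append((fit.params, reference_lines_from_theta(fit.params, coverage)))
    return BootstrapResult(
        replicates=tuple(replicates), n_requested=B, n_failed=n_failed, seed=seed
    )


def combine_bootstrap(result: BootstrapResult, ci_level: float = 0.95) -> BootstrapResult:
    """Combine replicates into final estimates with percentile CIs.

    Point estimates are arithmetic means of the replicate values; confidence
    intervals are empirical percentile intervals (linear-interpolation
    quantiles) at (1 - ci_level)/2 and 1 - (1 - ci_level)/2.
    """
    reps = result.replicates
    if len(reps) < 2:
        raise ValueError("combining requires at least 2 converged replicates")
    params = np.array([p.as_tuple() for p, _ in reps])
    mean_p = params.mean(axis=0)
    combined_params = BvnParams(*map(float, mean_p))
    biases = np.array([ln.bias for _, ln in reps])
    sds = np.array([ln.sd_diff for _, ln in reps])
    lowers = np.array([ln.lower for _, ln in reps])
    uppers = np.array([ln.upper for _, ln in reps])
    lo_q, hi_q = (1.0 - ci_level) / 2.0, 1.0 - (1.0 - ci_level) / 2.0

    def ci(values: np.ndarray) -> tuple[float, float]:
        return (float(np.quantile(values, lo_q)), float(np.quantile(values, hi_q)))

    combined_lines = ReferenceLines(
        bias=float(biases.mean()),
        sd_diff=float(sds.mean()),
        z_quantile=reps[0][1].z_quantile,
        lower=float(lowers.mean()),
        upper=float(uppers.mean()),
        ci_bias=ci(biases),
        ci_lower=ci(lowers),
        ci_upper=ci(uppers),
    )
    return BootstrapResult(
        replicates=reps,
        n_requested=result.n_requested,
        n_failed=result.n_failed,
        seed=result.seed,
        combined_params=combined_params,
        combined_lines=combined_lines,
    )


def stability_trace(
    result: BootstrapResult, digits: int = 2
) -> tuple[list[tuple[int, dict[str, float]]], int]:
    """Running combined estimates after each replicate prefix.

    Returns the trace ``[(prefix_length, {bias, lower, upper}), ...]`` and
    the first prefix length from which every reference-line estimate, rounded
    to ``digits`` decimal places, already equals its final rounded value and
    never changes again.
    """
    reps = result.replicates
    if len(reps) < 2:
        raise ValueError("stability trace requires at least 2 replicates")
    biases = np.array([ln.bias for _, ln in reps])
    lowers = np.array([ln.lower for _, ln in reps])
    uppers = np.array([ln.upper for _, ln in reps])
    counts = np.arange(1, len(reps) + 1)
    running = {
        "bias": np.cumsum(biases) / counts,
        "lower": np.cumsum(lowers) / counts,
        "upper": np.cumsum(uppers) / counts,
    }
    trace = [
        (int(k), {q: float(running[q][k - 1]) for q in running}) for k in counts
    ]
    stable_at = len(reps)
    rounded = {q: np.round(v, digits) for q, v in running.items()}
    for k in range(len(reps), 0, -1):
        if all(np.all(r[k - 1 :] == r[-1]) for r in rounded.values()):
            stable_at = k
        else:
            break
    return trace, stable_at
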