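# Methods

## Model

Paired measurements `(x_i, y_i)`, `i = 1..n`, are modelled through latent
variables `(X*, Y*)` that follow a bivariate normal distribution with
parameter vector `θ = (μx, μy, σx², σy², ρ)` on the analysis scale. For
concentration-type data the analysis scale is the log scale and the model is
a bivariate lognormal; the package stores all values and limits already
log-transformed and carries a `LOGNORMAL` flag as metadata only, so every
formula below applies unchanged.

An observation is recorded as its latent value when above its censoring
limit, and as a censoring annotation otherwise. Two designs are handled:

* **SINGLE** — fixed limits `Cx`, `Cy`; a pair falls in one of four
  categories according to which members are censored.
* **MULTI** — per-observation limits `C_{xi}`, `C_{yi1}`, `C_{yi2}`; the y
  member may also be interval-censored in `[C_{yi1}, C_{yi2}]`, giving six
  categories. Interval censoring of x is intentionally unsupported — the
  asymmetric design mirrors the practical setting (one method has a
  quantification band), and nothing in the likelihood would prevent the
  extension.

The log-likelihood sums block contributions over the category partition
(counts `n11, n01, n10, n00, n12, n02`):

| block | contribution per pair |
| --- | --- |
| both observed | `log f(x) + log f(y | x)` |
| x censored, y observed | `log f(y) + log Φ((Cx − μ_{x|y}) / σ_{x|y})` |
| x observed, y left-censored | `log f(x) + log Φ((Cy − μ_{y|x}) / σ_{y|x})` |
| both left-censored | `log P(X* ≤ Cx, Y* ≤ Cy)` |
| x observed, y interval | `log f(x) + log[Φ(ĉ₂) − Φ(ĉ₁)]` of the conditional |
| x censored, y interval | `log P(X* ≤ Cx, C_{y1} ≤ Y* ≤ C_{y2})` |

with the usual conditional-normal parameters
`μ_{x|y} = μx + ρ(σx/σy)(y − μy)`, `σ_{x|y}² = σx²(1 − ρ²)` (and
symmetrically). Rectangle probabilities are evaluated as differences of
bivariate normal CDF values with standardized bounds, which is algebraically
identical to integrating the marginal density times the conditional CDF over
the censored range; the quadrature form is retained in the test suite as an
independent oracle (relative agreement 1e−6 on fixtures spanning every
category). In the fixed-limit design the doubly censored block is a single
rectangle probability multiplied by `n00`, which keeps likelihood evaluation
cheap inside the optimizer.

## Estimation

The likelihood is maximized with Nelder–Mead on the unconstrained
parameterization `(μx, μy, log σx, log σy, atanh ρ)`, so no box constraints
are needed. The start point is the moment estimate of the naïve-substituted
sample — always defined and strictly inside the domain — and the search is
restarted once from a deterministic perturbation of the first optimum, taking
the better of the two. Correlations are clamped to `|ρ| ≤ 1 − 1e−9` and a
non-finite likelihood is returned as `−inf`, so boundary evaluations signal a
poor fit to the optimizer instead of raising. Identifiability requires at
least two fully observed pairs; samples below that threshold are rejected.
Nelder–Mead tolerances are `xatol 1e−8` / `fatol 1e−10`; the bivariate CDF is
used at scipy's default accuracy, which is well beyond the optimizer's
tolerance in all tested regimes. On fully observed data the fit reproduces
the closed-form moment estimates to 1e−4 or better.

Reference lines come in two conventions, kept deliberately distinct:

* **model-based**: `d = μy − μx`, `s = √(σx² + σy² − 2ρσxσy)`, limits
  `d ± z₀.₉₇₅·s`, with `z₀.₉₇₅` the exact 0.975 standard-normal quantile
  (1.959964…, not rounded to 1.96). Variances here are the divisor-`n` MLE.
* **empirical**: mean difference and divisor-`(n−1)` standard deviation of
  observed differences (classical Bland–Altman), used by the complete-case
  and naïve-substitution comparators.

Because of the `n` vs `n−1` convention the two routes differ by a factor
`√(n/(n−1))` in `s` even on uncensored data; this is intentional and visible
in the zero-censoring degenerate case.

Naïve substitution replaces a left-censored value by half its limit *on the
original measurement scale* (so `limit + log 0.5` on the log scale) and an
interval-censored value by the interval midpoint; the midpoint rule is this
package's extension of the comparator to interval censoring.

Rubin's-rule pooling of per-imputation empirical lines uses the large-sample
within-imputation variances `s²/n` for the bias and
`s²(1/n + z²/(2(n−1)))` for each limit, plus the between-imputation variance
with the standard `(1 + 1/m)` inflation; confidence intervals use a normal
approximation on the total variance.

## Bootstrap

Resampling is with replacement at the pair level, preserving the x–y
coupling and each pair's own limits. Each resample is refit by ML; resamples
with fewer than two complete pairs or a non-converged fit are discarded,
counted, and redrawn (budget: ten times the requested B). One root seed
spawns an independent substream per draw attempt, so results are bitwise
reproducible and independent of scheduling. Combined point estimates are the
arithmetic means of the replicate values (the replicate mean, rather than the
original-sample MLE, is the default combination rule); confidence intervals
are empirical percentile intervals with linear-interpolation quantiles.
BCa or studentized intervals are not implemented. A stability trace reports
the running combined estimates after each replicate prefix and the first
prefix from which all reference-line estimates, rounded to a requested
number of decimal places, stay at their final rounded value — the practical
tool for choosing B; the interpretation of `digits` as decimal places (not
significant digits) is a deliberate choice, matching how agreement limits
are read off a plot axis.

## Multiple imputation

Censored pairs are imputed from the fitted model — in the full pipeline,
from the combined bootstrap estimate `θ̂`:

* **one member censored** (left or interval): two-step inverse-CDF sampling
  from the conditional normal given the observed member. A uniform variate is
  drawn on the CDF-image of the censoring region (`[0, F(C)]` for left
  censoring, `[F(C₁), F(C₂)]` for interval censoring) and pushed through the
  conditional quantile function. Draws therefore respect the region by
  construction (closed bounds; boundary draws are accepted).
* **both members censored**: draws from the bivariate normal restricted to
  the rectangle `(−∞, C_x] × [C_{y1}, C_{y2}]` (with `C_{y1} = −∞` for pure
  left censoring). Rejection sampling from the unrestricted distribution is
  used while the rectangle probability is at least 0.01; below that the
  sampler switches to an exact conditional-chain construction — the
  rectangle's y-marginal CDF (a ratio of rectangle probabilities) is
  inverted numerically with Brent's method, then x is drawn from the
  truncated conditional. The chain route is exact, not approximate, so the
  switch threshold affects speed only; it exists because deep censoring
  under bootstrap-perturbed parameters makes plain rejection unbounded.

The default number of imputations for plotting is m = 20, a compromise in
the conventional 5–25 range for visual display: enough to show conditional
spread, few enough not to dominate the plot. Imputed markers are drawn
strictly smaller than observed markers for the same reason. Per-pair seed
substreams make the imputed sample bitwise reproducible.

## Synthetic data and the simulation study

The generator draws `n` latent pairs from the bivariate normal `θ` and
censors at **fixed theoretical quantiles**: `Cx = μx + σx·Φ⁻¹(p_x)`, and for
y a left-censoring quantile at `p_y` plus, optionally, an interval band
between the `p_y` and `p_y + p_int` quantiles. The achieved censored counts
are therefore Binomial(n, p) — the nominal proportions are expectations, not
per-sample exact counts. Defaults mirror the study conditions used
throughout: `μx = μy = 0`, `σx = σy = 1`, `ρ = 0.9` (lognormal on the
original scale), sample sizes {30, 50, 100}, censoring cells
{(10,10), (10,20), (10,30), (10,40), (30,30)}%, 2000 iterations — the
`paper_scale_grid()` helper builds this 15-cell design.

The study engine estimates the three reference-line quantities per iteration
with each method and scores bias and MSE against the closed-form truth
`reference_lines_from_theta(θ_true)`. The ML arm uses a single point fit per
iteration — bootstrap is for confidence intervals of a single analysis, not
part of the estimator being scored. Iterations with fewer than two complete
pairs are redrawn (affects only extreme-censoring small-n cells, counted);
iterations where any requested method fails are excluded for all methods and
counted, with a warning recorded above a 5% failure rate.

What the generator does *not* emulate: heteroscedastic measurement error,
mean-dependent bias (slope in the difference plot), skewness remaining after
log transform, ties or rounding at the readout resolution, or dependence
between censoring limits and the measured value beyond the fixed-quantile
mechanism. Passing tests therefore show correctness of the estimators under
the stated model, not robustness to model violation.

Default scales in the shipped tests and the acceptance script are reduced to
a single representative cell (n = 100, x 10% / y 30%, 200 iterations) —
chosen as the package's own desk-scale configuration; the full grid runs
through `censba simulate` or `paper_scale_grid()`.

## Numerical choices and degenerate inputs

* `log Φ` via `scipy.special.log_ndtr` (asymptotic-safe for arguments below
  −8, which occur with deep limits in bootstrap resamples).
* Rectangle probabilities below 1e−300, and zero-measure intervals
  (`C₁ = C₂` in the likelihood), raise an explicit degenerate-region error;
  sampling additionally requires rectangle mass ≥ 1e−12.
* A record claiming an observed value at or below its own limit is rejected
  at validation rather than silently re-censored — silent reclassification
  hides data errors.
* SINGLE-scenario samples must have homogeneous limits; heterogeneous limits
  require the MULTI scenario.
* Right-censoring and interval censoring of x are out of scope.

## Known limitations

* Standard errors come only from the bootstrap; no observed-information or
  sandwich variances.
* No confidence interval for ρ is exposed, although the fit estimates it.
* The bivariate normal assumption is not tested within the package; gross
  violations (e.g. heavy skew on the analysis scale) bias all model-based
  outputs. Alternative imputation models (chained equations, skewed
  conditionals) are deliberately not implemented.
* Percentile bootstrap intervals can undercover for small n and heavy
  censoring; the stability trace diagnoses Monte-Carlo error in B but not
  statistical coverage.
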