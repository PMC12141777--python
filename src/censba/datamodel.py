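"""Domain types and censoring vocabulary for paired-agreement analysis.

The central objects are a latent bivariate normal parameter vector
(:class:`BvnParams`), a paired sample with per-pair censoring annotations
(:class:`CensoredPair` / :class:`PairedSample`), and the category partition
used by the censored likelihood (:class:`PartitionedSample`).

Values and censoring limits are always stored on the *analysis* scale.  For
lognormal measurements this is the log scale; the :class:`Scale` flag is pure
metadata used for labelling and for conventions that refer to the original
measurement scale (such as substituting half the detection limit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional


class CensorStatus(str, Enum):
    """Observation status of a single member of a pair.

    ``INTERVAL`` is valid only for the y-variable: the model handles interval
    censoring of one method only, mirroring the asymmetric design in which a
    gravimetric-style method can produce "between two limits" readings while
    the reference method is either quantified or below its limit.
    """

    OBSERVED = "obs"
    LEFT = "left"
    INTERVAL = "interval"


class Scenario(str, Enum):
    """SINGLE: one fixed censoring limit per variable; MULTI: per-observation
    limits and possible interval censoring of y."""

    SINGLE = "single"
    MULTI = "multi"


class Scale(str, Enum):
    """Measurement-scale metadata. LOGNORMAL means stored values are logs."""

    NORMAL = "normal"
    LOGNORMAL = "lognormal"


class ValidationError(ValueError):
    """A pair or sample violates a structural invariant."""


@dataclass(frozen=True)
class BvnParams:
    """Parameters (mu_x, mu_y, var_x, var_y, rho) of the latent bivariate normal."""

    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    rho: float

    def __post_init__(self) -> None:
        if not (self.var_x > 0 and self.var_y > 0):
            raise ValidationError(
                f"variances must be strictly positive, got ({self.var_x}, {self.var_y})"
            )
        if not abs(self.rho) < 1:
            raise ValidationError(f"correlation must satisfy |rho| < 1, got {self.rho}")

    @property
    def sd_x(self) -> float:
        return math.sqrt(self.var_x)

    @property
    def sd_y(self) -> float:
        return math.sqrt(self.var_y)

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (self.mu_x, self.mu_y, self.var_x, self.var_y, self.rho)


@dataclass(frozen=True)
class ConditionalParams:
    """Mean and variance of one member of the pair given the other."""

    mean: float
    var: float

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValidationError(f"conditional variance must be positive, got {self.var}")

    @property
    def sd(self) -> float:
        return math.sqrt(self.var)


@dataclass(frozen=True)
class CensoredPair:
    """One (x, y) record with censoring status and limits.

    ``x_limit`` is the left-censoring limit for x (fixed ``Cx`` or
    per-observation), ``y_lower``/``y_upper`` are the lower/upper limits for
    y: a LEFT-censored y lies below ``y_lower``; an INTERVAL-censored y lies
    in ``[y_lower, y_upper]``.
    """

    x_value: Optional[float] = None
    x_status: CensorStatus = CensorStatus.OBSERVED
    x_limit: Optional[float] = None
    y_value: Optional[float] = None
    y_status: CensorStatus = CensorStatus.OBSERVED
    y_lower: Optional[float] = None
    y_upper: Optional[float] = None

    def validate(self) -> None:
        if self.x_status is CensorStatus.INTERVAL:
            raise ValidationError("interval censoring is supported for y only")
        if self.x_status is CensorStatus.OBSERVED:
            if self.x_value is None:
                raise ValidationError("observed x requires a value")
            if self.x_limit is not None and not self.x_value > self.x_limit:
                raise ValidationError(
                    f"observed x value {self.x_value} is not above its limit {self.x_limit}"
                )
        else:  # LEFT
            if self.x_limit is None:
                raise ValidationError("left-censored x requires a limit")
            if self.x_value is not None:
                raise ValidationError("left-censored x must not carry a value")
        if self.y_status is CensorStatus.OBSERVED:
            if self.y_value is None:
                raise ValidationError("observed y requires a value")
        elif self.y_status is CensorStatus.LEFT:
            if self.y_lower is None:
                raise ValidationError("left-censored y requires a lower limit")
            if self.y_value is not None:
                raise ValidationError("left-censored y must not carry a value")
        else:  # INTERVAL
            if self.y_lower is None or self.y_upper is None:
                raise ValidationError("interval-censored y requires both limits")
            if self.y_lower > self.y_upper:
                raise ValidationError("interval bounds reversed")
            if self.y_value is not None:
                raise ValidationError("interval-censored y must not carry a value")

    @property
    def category(self) -> str:
        """Likelihood category id: '11', '01', '10', '00', '12' or '02'."""
        x_cens = self.x_status is CensorStatus.LEFT
        if self.y_status is CensorStatus.OBSERVED:
            return "01" if x_cens else "11"
        if self.y_status is CensorStatus.LEFT:
            return "00" if x_cens else "10"
        return "02" if x_cens else "12"


#: Category block order used for the reordered likelihood.
CATEGORY_ORDER: tuple[str, ...] = ("11", "01", "10", "00", "12", "02")


@dataclass(frozen=True)
class PairedSample:
    """Ordered collection of censored pairs with scenario and scale metadata."""

    pairs: tuple[CensoredPair, ...]
    scenario: Scenario = Scenario.SINGLE
    scale: Scale = Scale.NORMAL

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", tuple(self.pairs))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class PartitionedSample:
    """The sample regrouped into likelihood category blocks."""

    blocks: dict[str, tuple[CensoredPair, ...]]
    scenario: Scenario = Scenario.SINGLE
    scale: Scale = Scale.NORMAL

    def count(self, category: str) -> int:
        return len(self.blocks[category])

    @property
    def counts(self) -> dict[str, int]:
        return {cat: len(self.blocks[cat]) for cat in CATEGORY_ORDER}

    @property
    def n(self) -> int:
        return sum(len(b) for b in self.blocks.values())

    def flatten(self) -> PairedSample:
        """Concatenate the blocks in canonical order back into a sample."""
        pairs: list[CensoredPair] = []
        for cat in CATEGORY_ORDER:
            pairs.extend(self.blocks[cat])
        return PairedSample(tuple(pairs), scenario=self.scenario, scale=self.scale)


@dataclass(frozen=True)
class ReferenceLines:
    """Bias line and limits of agreement of a mean-difference plot.

    ``lower = bias - z_quantile * sd_diff`` and symmetrically for ``upper``;
    optional confidence intervals are (low, high) tuples.
    """

    bias: float
    sd_diff: float
    z_quantile: float
    lower: float = field(default=math.nan)
    upper: float = field(default=math.nan)
    ci_bias: Optional[tuple[float, float]] = None
    ci_lower: Optional[tuple[float, float]] = None
    ci_upper: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.sd_diff < 0:
            raise ValidationError("sd of differences must be nonnegative")
        if math.isnan(self.lower):
            object.__setattr__(self, "lower", self.bias - self.z_quantile * self.sd_diff)
        if math.isnan(self.upper):
            object.__setattr__(self, "upper", self.bias + self.z_quantile * self.sd_diff)

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class BootstrapResult:
    """Replicate fits plus (optionally) the combined estimate.

    ``replicates`` holds one (params, lines) tuple per converged bootstrap
    sample; resamples that failed to fit were discarded and redrawn, with the
    discard count in ``n_failed``.
    """

    replicates: tuple[tuple[BvnParams, ReferenceLines], ...]
    n_requested: int
    n_failed: int
    seed: Optional[int] = None
    combined_params: Optional[BvnParams] = None
    combined_lines: Optional[ReferenceLines] = None


@dataclass(frozen=True)
class ImputedPoints:
    """Plot coordinates for one censored pair: m (mean, diff) points."""

    pair_index: int
    category: str
    draws: tuple[tuple[float, float], ...]  # underlying (x, y) draws

    @property
    def points(self) -> tuple[tuple[float, float], ...]:
        return tuple((0.5 * (x + y), y - x) for x, y in self.draws)


@dataclass(frozen=True)
class ImputedSample:
    """Observed plus multiply-imputed plotting coordinates."""

    observed_points: tuple[tuple[float, float], ...]
    imputed: tuple[ImputedPoints, ...]
    m: int

    @property
    def n_imputed_points(self) -> int:
        return sum(len(ip.draws) for ip in self.imputed)


def validate_sample(sample: PairedSample) -> PairedSample:
    """Check every pair invariant and the scenario constraints.

    Returns the sample unchanged; raises :class:`ValidationError` naming the
    index and rule of the first offending pair.
    """
    if len(sample.pairs) < 2:
        raise ValidationError("a paired sample requires at least 2 pairs")
    for i, pair in enumerate(sample.pairs):
        try:
            pair.validate()
        except ValidationError as exc:
            raise ValidationError(f"pair {i}: {exc}") from None
        if sample.scenario is Scenario.SINGLE and pair.y_status is CensorStatus.INTERVAL:
            raise ValidationError(f"pair {i}: interval censoring requires the MULTI scenario")
    if sample.scenario is Scenario.SINGLE:
        x_limits = {p.x_limit for p in sample.pairs if p.x_status is CensorStatus.LEFT}
        y_limits = {p.y_lower for p in sample.pairs if p.y_status is CensorStatus.LEFT}
        if len(x_limits) > 1 or len(y_limits) > 1:
            raise ValidationError("heterogeneous limits in SINGLE scenario")
    return sample


def partition_sample(sample: PairedSample) -> PartitionedSample:
    """Group pairs into the category blocks of the reordered likelihood.

    The partition is a bijection: flattening the blocks in canonical order
    yields a permutation of the input pairs.
    """
    blocks: dict[str, list[CensoredPair]] = {cat: [] for cat in CATEGORY_ORDER}
    for pair in sample.pairs:
        blocks[pair.category].append(pair)
    return PartitionedSample(
        blocks={cat: tuple(b) for cat, b in blocks.items()},
        scenario=sample.scenario,
        scale=sample.scale,
    )


def single_limits(part: PartitionedSample) -> tuple[Optional[float], Optional[float]]:
    """The common (Cx, Cy) of a SINGLE-scenario partition (None if no censoring)."""
    cx = cy = None
    for b in part.blocks.values():
        for p in b:
            if p.x_status is CensorStatus.LEFT:
                cx = p.x_limit
            if p.y_status is CensorStatus.LEFT:
                cy = p.y_lower
    return cx, cy


def substitute_pair(pair: CensoredPair, x_value: float | None, y_value: float | None) -> CensoredPair:
    """Return a fully observed copy of ``pair`` with censored members replaced."""
    out = pair
    if x_value is not None:
        out = replace(out, x_value=x_value, x_status=CensorStatus.OBSERVED, x_limit=None)
    if y_value is not None:
        out = replace(
            out, y_value=y_value, y_status=CensorStatus.OBSERVED, y_lower=None, y_upper=None
        )
    return out
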