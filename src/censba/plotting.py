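"""Mean-difference (Bland-Altman) plot rendering.

Observed pairs are plotted as full-size markers; multiply imputed censored
pairs as distinctly smaller markers so the imputed cloud does not visually
outweigh the measured data.  Reference lines (bias and limits of agreement)
are drawn horizontally, with optional confidence-interval bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .datamodel import ImputedSample, ReferenceLines

_CATEGORY_COLORS = {
    "01": "tab:orange",
    "10": "tab:green",
    "00": "tab:red",
    "12": "tab:purple",
    "02": "tab:brown",
}


@dataclass(frozen=True)
class PlotSpec:
    points: ImputedSample
    lines: ReferenceLines
    observed_size: float = 22.0
    imputed_size: float = 5.0
    observed_color: str = "0.25"
    line_color: str = "magenta"
    ci_color: str = "0.6"
    xlabel: str = "mean of methods"
    ylabel: str = "difference (y - x)"
    title: Optional[str] = None
    fmt: str = "png"

    def __post_init__(self) -> None:
        if not self.imputed_size < self.observed_size:
            raise ValueError("imputed markers must be strictly smaller than observed markers")
        if self.fmt not in {"png", "svg", "pdf"}:
            raise ValueError(f"unsupported output format {self.fmt!r}")


def render_ba_plot(spec: PlotSpec, path: str | Path) -> Path:
    """Render the plot described by ``spec`` and write it to ``path``."""
    pts = spec.points
    if not pts.observed_points and not pts.imputed:
        raise ValueError("nothing to plot: empty point set")
    fig, ax = plt.subplots(figsize=(6.4, 4.8))
    if pts.observed_points:
        mx = [m for m, _ in pts.observed_points]
        dy = [d for _, d in pts.observed_points]
        ax.scatter(mx, dy, s=spec.observed_size, c=spec.observed_color,
                   label="observed", zorder=3)
    seen: set[str] = set()
    for ip in pts.imputed:
        mx = [m for m, _ in ip.points]
        dy = [d for _, d in ip.points]
        label = f"imputed ({ip.category})" if ip.category not in seen else None
        seen.add(ip.category)
        ax.scatter(mx, dy, s=spec.imputed_size,
                   c=_CATEGORY_COLORS.get(ip.category, "tab:blue"),
                   alpha=0.6, label=label, zorder=2)
    ln = spec.lines
    for value, style in ((ln.bias, "-"), (ln.lower, "--"), (ln.upper, "--")):
        ax.axhline(value, color=spec.line_color, linestyle=style, zorder=4)
    for ci in (ln.ci_bias, ln.ci_lower, ln.ci_upper):
        if ci is not None:
            ax.axhspan(ci[0], ci[1], color=spec.ci_color, alpha=0.25, zorder=1)
    ax.set_xlabel(spec.xlabel)
    ax.set_ylabel(spec.ylabel)
    if spec.title:
        ax.set_title(spec.title)
    if pts.observed_points or pts.imputed:
        ax.legend(loc="best", fontsize=8)
    out = Path(path)
    fig.savefig(out, format=spec.fmt, dpi=150)
    plt.close(fig)
    return out
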