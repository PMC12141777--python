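"""CSV input/output with an explicit censoring dialect, plus JSON reports.

The CSV layout has one row per pair with columns
``x, x_status, x_limit, y, y_status, y_lower, y_upper``; statuses are
``obs`` / ``left`` / ``interval`` and inapplicable cells stay empty.
Censoring is encoded by status + limit columns rather than sentinel values,
so parsing is unambiguous and locale-independent (dot decimal separator).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

from . import __version__
from .datamodel import (
    BootstrapResult,
    BvnParams,
    CensoredPair,
    CensorStatus,
    PairedSample,
    ReferenceLines,
    Scale,
    Scenario,
    validate_sample,
)
from .estimation import FitResult

CSV_COLUMNS = ["x", "x_status", "x_limit", "y", "y_status", "y_lower", "y_upper"]
_STATUS = {"obs": CensorStatus.OBSERVED, "left": CensorStatus.LEFT, "interval": CensorStatus.INTERVAL}


class CsvFormatError(ValueError):
    """Malformed input row; the message carries the 1-based row number."""


def _parse_cell(cell: str, row: int, column: str) -> Optional[float]:
    cell = cell.strip()
    if cell == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise CsvFormatError(f"row {row}: non-numeric value {cell!r} in column {column!r}") from None


def read_sample_csv(
    path: str | Path,
    scenario: Scenario = Scenario.SINGLE,
    scale: Scale = Scale.NORMAL,
) -> PairedSample:
    """Read and validate a censored paired sample."""
    pairs: list[CensoredPair] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise CsvFormatError(f"missing columns: {sorted(missing)}")
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            for status_col in ("x_status", "y_status"):
                token = (row[status_col] or "").strip().lower()
                if token not in _STATUS:
                    raise CsvFormatError(
                        f"row {i}: unknown status token {row[status_col]!r} in {status_col!r}"
                    )
            pair = CensoredPair(
                x_value=_parse_cell(row["x"], i, "x"),
                x_status=_STATUS[row["x_status"].strip().lower()],
                x_limit=_parse_cell(row["x_limit"], i, "x_limit"),
                y_value=_parse_cell(row["y"], i, "y"),
                y_status=_STATUS[row["y_status"].strip().lower()],
                y_lower=_parse_cell(row["y_lower"], i, "y_lower"),
                y_upper=_parse_cell(row["y_upper"], i, "y_upper"),
            )
            try:
                pair.validate()
            except ValueError as exc:
                raise CsvFormatError(f"row {i}: {exc}") from None
            pairs.append(pair)
    return validate_sample(PairedSample(tuple(pairs), scenario=scenario, scale=scale))


def write_sample_csv(sample: PairedSample, path: str | Path) -> None:
    """Write a sample in the same dialect; round-trips losslessly."""

    def fmt(v: Optional[float]) -> str:
        return "" if v is None else repr(float(v))

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for p in sample.pairs:
            writer.writerow(
                [
                    fmt(p.x_value), p.x_status.value, fmt(p.x_limit),
                    fmt(p.y_value), p.y_status.value, fmt(p.y_lower), fmt(p.y_upper),
                ]
            )


def _lines_to_dict(lines: ReferenceLines) -> dict:
    out = {
        "bias": lines.bias,
        "sd_diff": lines.sd_diff,
        "lower": lines.lower,
        "upper": lines.upper,
        "z_quantile": lines.z_quantile,
    }
    for name in ("ci_bias", "ci_lower", "ci_upper"):
        ci = getattr(lines, name)
        if ci is not None:
            out[name] = list(ci)
    return out


def _params_to_dict(theta: BvnParams) -> dict:
    return {
        "mu_x": theta.mu_x, "mu_y": theta.mu_y,
        "var_x": theta.var_x, "var_y": theta.var_y, "rho": theta.rho,
    }


def write_results(
    path: str | Path,
    fit: Optional[FitResult] = None,
    bootstrap: Optional[BootstrapResult] = None,
    lines: Optional[ReferenceLines] = None,
    extra: Optional[dict] = None,
) -> dict:
    """Write a JSON analysis report; fields absent from the analysis are omitted."""
    report: dict = {"software_version": __version__}
    if fit is not None:
        report["fit"] = {
            "params": _params_to_dict(fit.params),
            "loglik": fit.loglik,
            "converged": fit.converged,
            "n_evals": fit.n_evals,
        }
    if bootstrap is not None:
        report["bootstrap"] = {
            "n_requested": bootstrap.n_requested,
            "n_failed": bootstrap.n_failed,
            "n_replicates": len(bootstrap.replicates),
        }
        if bootstrap.seed is not None:
            report["bootstrap"]["seed"] = bootstrap.seed
        if bootstrap.combined_params is not None:
            report["bootstrap"]["combined_params"] = _params_to_dict(bootstrap.combined_params)
        if bootstrap.combined_lines is not None:
            report["bootstrap"]["combined_lines"] = _lines_to_dict(bootstrap.combined_lines)
    if lines is not None:
        report["reference_lines"] = _lines_to_dict(lines)
    if extra:
        report.update(extra)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
    return report


def read_results(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
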