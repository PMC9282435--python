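"""Output surfaces: cumulative/annual tables, per-100k rates, summary statistics.

Tables mirror the published layout: five-yearly interval columns over the
horizon, rows per disease (plus a combined-diseases row) and per sex (plus a
total row), each cell carrying its Monte Carlo half-width. Combined and
total cells are computed from unrounded replicate-level values and only
rounded for display, so additivity holds exactly in the machine-readable
outputs.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import AttributableResult
from .errors import CoverageError
from .strata import DISEASES, SEXES

_MEASURES = ("incident", "prevalent", "cost")


def _interval_years(years: np.ndarray, interval_years: int) -> list[int]:
    start = int(years[0])
    out = [int(y) for y in years if (int(y) - start) % interval_years == 0]
    return out


def _hw(stack: np.ndarray) -> float:
    """Half-width of a per-replicate 1-D stack: 1.96 * SD / sqrt(R)."""
    r = len(stack)
    if r < 2:
        return float("nan")
    return float(1.96 * np.std(stack, ddof=1) / np.sqrt(r))


def _stratified_table(
    result: AttributableResult, measure: str, cumulative: bool, interval_years: int
) -> pd.DataFrame:
    if measure not in _MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {_MEASURES}")
    reps = getattr(result, f"{measure}_reps")  # (R, Y, 2, 8, 3)
    years = result.years
    wanted = _interval_years(years, interval_years)
    if cumulative:
        # cumulative sums require an unbroken annual series
        if not np.array_equal(np.diff(years), np.ones(len(years) - 1)):
            raise CoverageError("result years must cover the horizon without gaps")
        series = np.cumsum(reps, axis=1)
    else:
        series = reps
    year_pos = {int(y): i for i, y in enumerate(years)}

    rows = []
    by_sex = series.sum(axis=3)  # (R, Y, 2, 3): summed over age bands
    for di, disease in enumerate(list(DISEASES) + ["combined"]):
        if disease == "combined":
            cells = by_sex.sum(axis=3)  # (R, Y, 2)
        else:
            cells = by_sex[..., di]
        for si, sex in enumerate(list(SEXES) + ["total"]):
            stack_t = cells.sum(axis=2) if sex == "total" else cells[..., si]  # (R, Y)
            for y in wanted:
                col = stack_t[:, year_pos[y]]
                rows.append(
                    {
                        "disease": disease,
                        "sex": sex,
                        "year": y,
                        "value": float(col.mean()),
                        "half_width": _hw(col),
                    }
                )
    return pd.DataFrame(rows)


def cumulative_table(
    result: AttributableResult, measure: str = "incident", interval_years: int = 5
) -> pd.DataFrame:
    """Cumulative attributable outcomes at interval years.

    Rows cover every disease plus a combined-diseases row, and male, female
    and total; values are running sums of annual cells from the start year.
    """
    return _stratified_table(result, measure, cumulative=True, interval_years=interval_years)


def annual_table(
    result: AttributableResult, measure: str = "incident", interval_years: int = 1
) -> pd.DataFrame:
    """Annual attributable outcomes (default: every year)."""
    return _stratified_table(result, measure, cumulative=False, interval_years=interval_years)


def rate_per_100k(count: float, population: float) -> float:
    """Cases per 100,000 population."""
    if population <= 0:
        raise ValueError(f"population headcount must be > 0, got {population}")
    return 1e5 * count / population


def share_statistic(part: float, whole: float) -> float:
    """Percentage share of a whole (e.g. the male share of a total burden)."""
    if whole <= 0:
        raise ValueError(f"whole must be > 0, got {whole}")
    return 100.0 * part / whole


def percent_change(v_start: float, v_end: float) -> float:
    """Percentage change from a (positive) starting value."""
    if v_start <= 0:
        raise ValueError(f"starting value must be > 0, got {v_start}")
    return 100.0 * (v_end - v_start) / v_start


def age_sex_table(
    result: AttributableResult, measure: str = "incident", cumulative: bool = True
) -> pd.DataFrame:
    """Fully disaggregated (year, sex, age band, disease) table."""
    from .strata import REPORTING_BANDS

    reps = getattr(result, f"{measure}_reps")
    series = np.cumsum(reps, axis=1) if cumulative else reps
    rows = []
    for yi, year in enumerate(result.years):
        for si, sex in enumerate(SEXES):
            for bi, band in enumerate(REPORTING_BANDS):
                for di, disease in enumerate(DISEASES):
                    col = series[:, yi, si, bi, di]
                    rows.append(
                        {
                            "year": int(year),
                            "sex": sex,
                            "age_group": band,
                            "disease": disease,
                            "value": float(col.mean()),
                            "half_width": _hw(col),
                        }
                    )
    return pd.DataFrame(rows)


def write_outputs(
    tables: dict[str, pd.DataFrame],
    outdir: str | Path,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write output tables as CSV plus a machine-readable run manifest.

    The manifest records whatever run metadata the caller supplies (seed,
    replicate count, config digest) plus the half-width method; a
    ``config`` entry is digested to SHA-256 for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False)
        written[name] = path
    meta = dict(manifest or {})
    meta.setdefault("half_width_method", "1.96 * SD / sqrt(R) over replicate runs")
    if "config" in meta:
        blob = json.dumps(meta["config"], sort_keys=True, default=str)
        meta["config_digest"] = hashlib.sha256(blob.encode()).hexdigest()
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    written["manifest"] = path
    return written
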