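"""Delimited-text readers and writers for every input surface.

All inputs are plain CSV plus one YAML bundle file; schemas are validated on
read and documented here:

``surveys.csv``
    ``year, sex, age_group, p_healthy, p_pre_obese, p_obese, n_sample`` —
    missing (year x stratum) rows are tolerated (e.g. a wave that excluded
    older respondents).
``rates.csv``
    ``disease, measure, sex, age_group, value, units`` with units one of
    ``per_100000 | per_person_year | proportion``.
``relative_risks.csv``
    ``disease, category, rr`` — must include the healthy reference rows.
``pyramid.csv``
    ``sex, age, count`` (single-year ages).
``fertility.csv``
    ``age, value, units`` (births per woman-year).
``mortality.csv``
    ``sex, age, value, units`` (deaths per person-year).
``projected_population.csv``
    ``year, sex, age_group, count`` (five-year bands).
``bundle.yaml``
    file names for the above plus the cost constants and optional
    simulation settings.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .bmi_trends import SurveyPoint
from .costing import CostSchedule
from .demography import DemographyInputs
from .disease_model import RateTable, RelativeRiskTable
from .engine import InputBundle, SimulationConfig
from .errors import SchemaError

_RATE_UNITS = {"per_100000": 1e-5, "per_person_year": 1.0}


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} is missing columns {missing}")


def read_survey_csv(path: str | Path) -> list[SurveyPoint]:
    df = pd.read_csv(path)
    _require_columns(
        df,
        ["year", "sex", "age_group", "p_healthy", "p_pre_obese", "p_obese", "n_sample"],
        "survey file",
    )
    points = []
    for _, row in df.iterrows():
        points.append(
            SurveyPoint(
                year=int(row["year"]),
                sex=str(row["sex"]),
                age_group=str(row["age_group"]),
                proportions=(
                    float(row["p_healthy"]),
                    float(row["p_pre_obese"]),
                    float(row["p_obese"]),
                ),
                n_sample=int(row["n_sample"]),
            )
        )
    return points


def write_survey_csv(points: list[SurveyPoint], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "year": p.year,
                "sex": p.sex,
                "age_group": p.age_group,
                "p_healthy": p.proportions[0],
                "p_pre_obese": p.proportions[1],
                "p_obese": p.proportions[2],
                "n_sample": p.n_sample,
            }
            for p in points
        ]
    )
    df.to_csv(path, index=False)


def _read_rate_column(path: str | Path, cols: list[str], name: str) -> pd.DataFrame:
    """Read a vital-rate CSV with an explicit units column; normalise to per person-year."""
    df = pd.read_csv(path)
    _require_columns(df, cols + ["value", "units"], name)
    bad = ~df["units"].isin(_RATE_UNITS)
    if bad.any():
        raise SchemaError(
            f"{name}: unknown units {sorted(df.loc[bad, 'units'].unique())}; "
            f"expected one of {sorted(_RATE_UNITS)}"
        )
    df = df.copy()
    df["rate"] = df["value"].astype(float) * df["units"].map(_RATE_UNITS)
    return df[cols + ["rate"]]


def read_demography(
    pyramid_path: str | Path,
    fertility_path: str | Path,
    mortality_path: str | Path,
    projected_path: str | Path,
) -> DemographyInputs:
    pyramid = pd.read_csv(pyramid_path)
    _require_columns(pyramid, ["sex", "age", "count"], "pyramid file")
    fertility = _read_rate_column(fertility_path, ["age"], "fertility file")
    mortality = _read_rate_column(mortality_path, ["sex", "age"], "mortality file")
    projected = pd.read_csv(projected_path)
    _require_columns(projected, ["year", "sex", "age_group", "count"], "projected population file")
    return DemographyInputs(
        pyramid=pyramid, fertility=fertility, mortality=mortality, projected=projected
    )


def read_rates_csv(path: str | Path) -> RateTable:
    return RateTable(pd.read_csv(path))


def read_relative_risks_csv(path: str | Path) -> RelativeRiskTable:
    return RelativeRiskTable.from_frame(pd.read_csv(path))


def write_bundle(
    bundle: InputBundle,
    outdir: str | Path,
    rates: pd.DataFrame,
    rr: pd.DataFrame,
) -> Path:
    """Write a full input bundle as CSV files plus ``bundle.yaml``.

    ``rates`` and ``rr`` are the tidy source frames (RateTable normalises
    units internally and is not written back).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_survey_csv(bundle.surveys, outdir / "surveys.csv")
    rates.to_csv(outdir / "rates.csv", index=False)
    rr.to_csv(outdir / "relative_risks.csv", index=False)
    bundle.demography.pyramid.to_csv(outdir / "pyramid.csv", index=False)
    fert = bundle.demography.fertility.copy()
    fert = fert.rename(columns={"rate": "value"})
    fert["units"] = "per_person_year"
    fert.to_csv(outdir / "fertility.csv", index=False)
    mort = bundle.demography.mortality.copy().rename(columns={"rate": "value"})
    mort["units"] = "per_person_year"
    mort.to_csv(outdir / "mortality.csv", index=False)
    bundle.demography.projected.to_csv(outdir / "projected_population.csv", index=False)
    meta = {
        "files": {
            "surveys": "surveys.csv",
            "rates": "rates.csv",
            "relative_risks": "relative_risks.csv",
            "pyramid": "pyramid.csv",
            "fertility": "fertility.csv",
            "mortality": "mortality.csv",
            "projected_population": "projected_population.csv",
        },
        "costs": {
            "annual_cost_t2dm": bundle.costs.annual_cost_t2dm,
            "annual_cost_cld": bundle.costs.annual_cost_cld,
            "terminal_cost_liver_cancer": bundle.costs.terminal_cost_liver_cancer,
            "currency_year": bundle.costs.currency_year,
        },
    }
    with open(outdir / "bundle.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    return outdir / "bundle.yaml"


def load_bundle(bundle_yaml: str | Path) -> InputBundle:
    """Load a bundle written by :func:`write_bundle` (or hand-assembled)."""
    bundle_yaml = Path(bundle_yaml)
    with open(bundle_yaml) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or "files" not in meta or "costs" not in meta:
        raise SchemaError("bundle.yaml must contain 'files' and 'costs' sections")
    base = bundle_yaml.parent
    files = meta["files"]
    demography = read_demography(
        base / files["pyramid"],
        base / files["fertility"],
        base / files["mortality"],
        base / files["projected_population"],
    )
    costs = CostSchedule(**meta["costs"])
    return InputBundle(
        demography=demography,
        surveys=read_survey_csv(base / files["surveys"]),
        rates=read_rates_csv(base / files["rates"]),
        relative_risks=read_relative_risks_csv(base / files["relative_risks"]),
        costs=costs,
    )


def load_simulation_config(bundle_yaml: str | Path, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from the YAML's optional
    ``simulation`` section, with keyword overrides taking precedence."""
    with open(bundle_yaml) as fh:
        meta = yaml.safe_load(fh) or {}
    settings = dict(meta.get("simulation", {}) or {})
    settings.update(overrides)
    return SimulationConfig(**settings)
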