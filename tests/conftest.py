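"""Shared fixtures: default synthetic bundle and an analytically tractable cohort."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from obesim import (
    CostSchedule,
    DemographyInputs,
    InputBundle,
    RateTable,
    RelativeRiskTable,
    SimulationConfig,
    SurveyPoint,
    generate_saudi_like_defaults,
    prepare_trend_model,
)
from obesim.strata import AGE_BANDS, AGE_TO_BAND, MAX_AGE, REPORTING_BANDS, SEXES

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_bundle() -> InputBundle:
    """Noiseless default bundle anchored at the published prevalence figures."""
    return generate_saudi_like_defaults(seed=1)


@pytest.fixture(scope="session")
def default_trend(default_bundle):
    cfg = SimulationConfig(n_sim=1000, seed=1)
    return prepare_trend_model(default_bundle, cfg)


def make_cohort_bundle(
    incidence_per_100k: float = 1000.0,
    rr_t2dm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    projected_per_cell: float = 1_000_000.0,
    proportions: tuple[float, float, float] = (0.4, 0.35, 0.25),
) -> InputBundle:
    """Closed single-age cohort: everyone starts at age 20 in 2020.

    Vital rates are zero and only T2DM has nonzero incidence (constant
    across strata), so the cumulative count after T years has the closed
    form N (1 - exp(-lambda T)). The projected population is nonzero only
    in the band the cohort occupies each year, which the aging trajectory
    determines exactly.
    """
    ages = np.arange(MAX_AGE + 1)
    pyramid = pd.DataFrame(
        [(sex, 20, 1.0) for sex in SEXES], columns=["sex", "age", "count"]
    )
    fertility = pd.DataFrame({"age": ages, "rate": np.zeros(MAX_AGE + 1)})
    mortality = pd.DataFrame(
        [(sex, int(a), 0.0) for sex in SEXES for a in ages],
        columns=["sex", "age", "rate"],
    )
    rows = []
    for year in range(2020, 2041):
        occupied = AGE_BANDS[AGE_TO_BAND[20 + year - 2020]]
        for sex in SEXES:
            for band in REPORTING_BANDS:
                rows.append(
                    (year, sex, band, projected_per_cell if band == occupied else 0.0)
                )
    projected = pd.DataFrame(rows, columns=["year", "sex", "age_group", "count"])
    demography = DemographyInputs(
        pyramid=pyramid, fertility=fertility, mortality=mortality, projected=projected
    )
    surveys = [
        SurveyPoint(year=y, sex=sex, age_group=band, proportions=proportions, n_sample=10**6)
        for y in (2005, 2013)
        for sex in SEXES
        for band in REPORTING_BANDS
    ]
    rates = RateTable(
        pd.DataFrame(
            [
                ("t2dm", "incidence", sex, band, incidence_per_100k, "per_100000")
                for sex in SEXES
                for band in REPORTING_BANDS
            ],
            columns=["disease", "measure", "sex", "age_group", "value", "units"],
        )
    )
    rr = RelativeRiskTable(
        {
            "t2dm": rr_t2dm,
            "chronic_liver_disease": (1.0, 1.0, 1.0),
            "liver_cancer": (1.0, 1.0, 1.0),
        }
    )
    costs = CostSchedule(
        annual_cost_t2dm=2704.41,
        annual_cost_cld=8923.62,
        terminal_cost_liver_cancer=13259.80,
    )
    return InputBundle(
        demography=demography, surveys=surveys, rates=rates,
        relative_risks=rr, costs=costs,
    )


@pytest.fixture(scope="session")
def cohort_bundle() -> InputBundle:
    return make_cohort_bundle()
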