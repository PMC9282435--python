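"""Internally consistent synthetic input bundles with known ground truth.

The real model runs on national survey, registry and burden-of-disease
tables that are not redistributable; every pipeline stage here is exercised
instead on generated inputs whose generating parameters are known exactly.
The generator emulates the statistical structure of those sources:

* cross-sectional BMI-category surveys at a few years (default 2005, 2011,
  2013, 2016 — with the 50+ strata deliberately absent from the 2016 wave,
  mirroring a small-sample exclusion the loaders must tolerate), with
  multinomial sampling noise around a known log-odds time trend;
* age/sex-stratified disease incidence, prevalence and mortality tables
  (per 100,000);
* relative risks per BMI category;
* a population pyramid, fertility and all-cause mortality schedules, and a
  projected national population;
* per-patient annual/terminal cost constants.

The default magnitudes sit in the realistic range for a Gulf working-age
population: 2013 obesity prevalence anchored at 24.1% (men) and 33.5%
(women), chronic-liver-disease incidence 10.5 and mortality 1.2 per
100,000, and a 20-59 projected population of ~34.8 million in 2020.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bmi_trends import TIME_ORIGIN, SurveyPoint, _softmax3
from .costing import CostSchedule
from .demography import DemographyInputs
from .disease_model import RateTable, RelativeRiskTable
from .engine import InputBundle
from .errors import ConfigurationError
from .strata import DISEASES, MAX_AGE, REPORTING_BANDS, SEXES

DEFAULT_SURVEY_YEARS = (2005, 2011, 2013, 2016)


@dataclass
class GroundTruth:
    """Generating parameters for one synthetic input bundle.

    ``trend`` maps (sex, age band) to linear log-odds parameters
    ``(a_pre, b_pre, a_obese, b_obese)`` against ``year - 2010`` with healthy
    weight as the softmax reference. Disease rate values are per 100,000
    person-years (prevalence: per-100,000 persons).
    """

    trend: dict[tuple[str, str], np.ndarray]
    rates: dict[tuple[str, str], np.ndarray]  # (disease, measure) -> (2, 8) per-100k
    relative_risks: dict[str, tuple[float, float, float]]
    costs: CostSchedule
    mortality: np.ndarray  # (2, MAX_AGE+1) per person-year
    fertility: np.ndarray  # (MAX_AGE+1,) births per woman-year
    pyramid: np.ndarray  # (2, MAX_AGE+1) relative counts
    projected_base: np.ndarray  # (2, 8) headcount in 2020 for reporting bands
    projected_growth: float = 0.015  # annual growth of the projected population
    survey_years: tuple[int, ...] = DEFAULT_SURVEY_YEARS
    survey_n_sample: int | None = 2000  # None => noiseless proportions
    exclude_50plus_year: int | None = 2016
    horizon: tuple[int, int] = (2020, 2040)

    def __post_init__(self) -> None:
        if (self.mortality < 0).any() or (self.mortality > 1).any():
            raise ValueError("ground-truth mortality rates must lie in [0, 1]")
        if (self.fertility < 0).any() or (self.fertility > 1).any():
            raise ValueError("ground-truth fertility rates must lie in [0, 1]")
        if (self.pyramid < 0).any():
            raise ValueError("ground-truth pyramid counts must be >= 0")

    def category_probabilities(self, sex: str, age_group: str, year: float) -> np.ndarray:
        """True category probabilities implied by the trend parameters."""
        a_pre, b_pre, a_ob, b_ob = self.trend[(sex, age_group)]
        tau = year - TIME_ORIGIN
        return _softmax3(a_pre + b_pre * tau, a_ob + b_ob * tau)


def _logit_anchor(p_pre: float, p_ob: float, anchor_year: float,
                  b_pre: float, b_ob: float) -> np.ndarray:
    """Linear log-odds parameters hitting (p_pre, p_ob) at ``anchor_year``."""
    p_h = 1.0 - p_pre - p_ob
    if p_h <= 0:
        raise ConfigurationError("anchor proportions leave no healthy mass")
    tau = anchor_year - TIME_ORIGIN
    a_pre = np.log(p_pre / p_h) - b_pre * tau
    a_ob = np.log(p_ob / p_h) - b_ob * tau
    return np.array([a_pre, b_pre, a_ob, b_ob])


def make_default_truth(
    obesity_2013: tuple[float, float] = (0.241, 0.335),
    pre_obesity_2013: tuple[float, float] = (0.35, 0.30),
    obesity_slopes: tuple[float, float] = (0.025, -0.005),
    pre_obesity_slopes: tuple[float, float] = (0.005, 0.0),
    survey_n_sample: int | None = 2000,
) -> GroundTruth:
    """Construct the default ground truth.

    BMI trends are anchored at the 2013 national prevalence estimates
    (obesity 24.1% of men, 33.5% of women), rising for men and roughly flat
    to slightly falling for women. The same trend is used across age bands;
    the per-stratum fitting machinery does not know that.
    """
    trend: dict[tuple[str, str], np.ndarray] = {}
    for si, sex in enumerate(SEXES):
        params = _logit_anchor(
            pre_obesity_2013[si], obesity_2013[si], 2013.0,
            pre_obesity_slopes[si], obesity_slopes[si],
        )
        for band in REPORTING_BANDS:
            trend[(sex, band)] = params.copy()

    bands = np.arange(len(REPORTING_BANDS))
    rates: dict[tuple[str, str], np.ndarray] = {}
    # T2DM: incidence rises steeply with age; men somewhat higher than women.
    t2dm = 300.0 + 150.0 * bands
    rates[("t2dm", "incidence")] = np.vstack([t2dm, 0.8 * t2dm])
    # Chronic liver disease: NASH-cirrhosis-like flat rates.
    rates[("chronic_liver_disease", "incidence")] = np.full((2, 8), 10.5)
    rates[("chronic_liver_disease", "prevalence")] = np.full((2, 8), 500.0)
    rates[("chronic_liver_disease", "mortality")] = np.full((2, 8), 1.2)
    # Liver cancer: rare in the working-age range, rising with age.
    canc = 0.5 + 0.5 * bands
    rates[("liver_cancer", "incidence")] = np.vstack([canc, 0.6 * canc])
    rates[("liver_cancer", "mortality")] = 0.8 * np.vstack([canc, 0.6 * canc])

    ages = np.arange(MAX_AGE + 1, dtype=float)
    gompertz = np.minimum(0.6, 2e-4 + 5e-4 * np.exp(0.07 * ages))
    mortality = np.vstack([gompertz, 0.75 * gompertz])
    fertility = np.zeros(MAX_AGE + 1)
    fertility[15:50] = 0.08  # TFR ~ 2.8

    shape = np.exp(-0.025 * ages)
    pyramid = np.vstack([1.1 * shape, 0.9 * shape])  # male surplus

    # 20-59 projected population ~34.81M in 2020, split by the pyramid shape
    in_band = pyramid[:, 20:60].reshape(2, 8, 5).sum(axis=2)
    projected_base = 34_810_000.0 * in_band / in_band.sum()

    return GroundTruth(
        trend=trend,
        rates=rates,
        relative_risks={
            "t2dm": (1.0, 3.0, 7.0),
            "chronic_liver_disease": (1.0, 2.0, 5.0),
            "liver_cancer": (1.0, 1.5, 2.0),
        },
        costs=CostSchedule(
            annual_cost_t2dm=2704.41,
            annual_cost_cld=8923.62,
            terminal_cost_liver_cancer=13259.80,
        ),
        mortality=mortality,
        fertility=fertility,
        pyramid=pyramid,
        projected_base=projected_base,
        survey_n_sample=survey_n_sample,
    )


def generate_survey_points(truth: GroundTruth, rng: np.random.Generator) -> list[SurveyPoint]:
    """Survey points around the truth trend with multinomial noise.

    With ``survey_n_sample=None`` the emitted proportions equal the truth
    exactly (the noiseless limit); otherwise each (year, sex, band) cell is
    a multinomial draw of the stated sample size.
    """
    points: list[SurveyPoint] = []
    for year in truth.survey_years:
        for sex in SEXES:
            for band in REPORTING_BANDS:
                if (
                    truth.exclude_50plus_year is not None
                    and year == truth.exclude_50plus_year
                    and int(band.split("-")[0]) >= 50
                ):
                    continue  # small-sample exclusion of 50+ strata
                p = truth.category_probabilities(sex, band, year)
                if truth.survey_n_sample is None:
                    props, n = tuple(p), 10**9
                else:
                    n = truth.survey_n_sample
                    draw = rng.multinomial(n, p)
                    props = tuple(draw / n)
                points.append(
                    SurveyPoint(year=year, sex=sex, age_group=band,
                                proportions=props, n_sample=n)
                )
    return points


def _demography_inputs(truth: GroundTruth) -> DemographyInputs:
    ages = np.arange(MAX_AGE + 1)
    pyramid = pd.DataFrame(
        [(sex, int(a), float(truth.pyramid[si, a]))
         for si, sex in enumerate(SEXES) for a in ages],
        columns=["sex", "age", "count"],
    )
    fertility = pd.DataFrame(
        {"age": ages, "rate": truth.fertility}
    )
    mortality = pd.DataFrame(
        [(sex, int(a), float(truth.mortality[si, a]))
         for si, sex in enumerate(SEXES) for a in ages],
        columns=["sex", "age", "rate"],
    )
    y0, y1 = truth.horizon
    rows = []
    for year in range(y0, y1 + 1):
        growth = (1.0 + truth.projected_growth) ** (year - y0)
        for si, sex in enumerate(SEXES):
            for bi, band in enumerate(REPORTING_BANDS):
                rows.append((year, sex, band, truth.projected_base[si, bi] * growth))
    projected = pd.DataFrame(rows, columns=["year", "sex", "age_group", "count"])
    return DemographyInputs(
        pyramid=pyramid, fertility=fertility, mortality=mortality, projected=projected
    )


def rates_frame(truth: GroundTruth) -> pd.DataFrame:
    """Tidy per-100,000 rate table for the truth's disease epidemiology."""
    rows = []
    for (disease, measure), arr in truth.rates.items():
        for si, sex in enumerate(SEXES):
            for bi, band in enumerate(REPORTING_BANDS):
                rows.append((disease, measure, sex, band, float(arr[si, bi]), "per_100000"))
    return pd.DataFrame(
        rows, columns=["disease", "measure", "sex", "age_group", "value", "units"]
    )


def relative_risk_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for disease in DISEASES:
        for ci, cat in enumerate(("healthy", "pre_obese", "obese")):
            rows.append((disease, cat, truth.relative_risks[disease][ci]))
    return pd.DataFrame(rows, columns=["disease", "category", "rr"])


def generate_input_bundle(
    truth: GroundTruth, seed: int, outdir: str | Path | None = None
) -> InputBundle:
    """Emit a complete input bundle (optionally also as CSV files).

    The bundle round-trips through the package's loaders; the same seed
    yields byte-identical files.
    """
    rng = np.random.default_rng(seed)
    surveys = generate_survey_points(truth, rng)
    bundle = InputBundle(
        demography=_demography_inputs(truth),
        surveys=surveys,
        rates=RateTable(rates_frame(truth)),
        relative_risks=RelativeRiskTable(dict(truth.relative_risks)),
        costs=truth.costs,
    )
    if outdir is not None:
        from . import io as obesim_io

        obesim_io.write_bundle(bundle, outdir, rates=rates_frame(truth),
                               rr=relative_risk_frame(truth))
    return bundle


def generate_saudi_like_defaults(
    seed: int, outdir: str | Path | None = None
) -> InputBundle:
    """Default bundle anchored at the published national prevalence figures.

    2013 obesity prevalence is 24.1% (men) and 33.5% (women) in the emitted
    survey file (the default generator is noiseless so the anchors are
    exact), and chronic-liver-disease incidence/mortality echo the reported
    10.5 and 1.2 per 100,000.
    """
    truth = make_default_truth(survey_n_sample=None)
    return generate_input_bundle(truth, seed, outdir)
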