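"""Scenario orchestration: annual-step runs, counterfactual pairing, replicates.

One scenario run executes, for every year of the horizon, the fixed event
order: vital update (background deaths, births) -> BMI category assignment
-> disease contraction -> disease deaths -> cost accrual -> end-of-year
tallies. The attributable burden is the cell-wise difference between a
baseline run and a zero-obesity counterfactual run of the same replicate,
coupled through common random numbers: both runs consume identical uniform
variates per (individual, year, purpose), which removes most Monte Carlo
noise from the difference and makes the counterfactual's incidence at most
the baseline's whenever relative risks are >= 1.

Per-category hazards are always partitioned against the *baseline* category
probabilities, so the healthy-category hazard is calibrated to the observed
population rates; the counterfactual changes only who is exposed.

Monte Carlo error: replicate runs with independent seeds give per-cell
half-widths ``1.96 * SD / sqrt(R)``. These quantify simulation noise only,
not parameter uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bmi_trends import CategoryTrendModel, SurveyPoint, fit_category_trend
from .costing import CostSchedule, accrue_annual_costs
from .demography import (
    DemographyInputs,
    annual_vital_update,
    build_initial_population,
    scaling_weights,
)
from .disease_model import (
    RateTable,
    RelativeRiskTable,
    annual_probability,
    apply_case_fatality,
    contract_diseases,
    derive_case_fatality,
    partition_incidence,
)
from .errors import ConfigurationError, CoverageError
from .rng import RandomStreams, spawn_replicate_seeds
from .strata import (
    AGE_TO_BAND,
    CLD,
    DISEASES,
    LIVER_CANCER,
    N_DISEASES,
    N_REPORTING_BANDS,
    REPORTING_BANDS,
    REPORTING_BAND_INDICES,
    SEXES,
)

SCENARIOS = ("baseline", "counterfactual")

_FIRST_REP_BAND = REPORTING_BAND_INDICES[0]
_LAST_REP_BAND = REPORTING_BAND_INDICES[-1]


@dataclass(frozen=True)
class SimulationConfig:
    """Run-level settings.

    ``n_sim`` defaults to a desk-scale 10^5 individuals; the model design
    scales to 10^8 by configuration only (runtime grows linearly).
    """

    start_year: int = 2020
    end_year: int = 2040
    n_sim: int = 100_000
    n_replicates: int = 10
    seed: int = 12345
    scenario: str = "baseline"
    functional_form: str = "saturating"
    logodds_floor: float = -20.0
    use_common_random_numbers: bool = True
    cancer_survival_years: float = 1.0

    def __post_init__(self) -> None:
        if self.start_year > self.end_year:
            raise ConfigurationError("start_year must be <= end_year")
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


@dataclass
class InputBundle:
    """Validated inputs for one simulation: demography, surveys, rates, RRs, costs."""

    demography: DemographyInputs
    surveys: list[SurveyPoint]
    rates: RateTable
    relative_risks: RelativeRiskTable
    costs: CostSchedule


@dataclass
class ScenarioResult:
    """Stratified tallies from one scenario run.

    Arrays are indexed ``(year, sex, reporting band[, disease])``; ``incident``
    counts first onsets in the year, ``prevalent`` and ``headcount`` are
    end-of-year states, ``cost`` is the USD accrued in the year. ``*_scaled``
    are rescaled to the projected national population via per-stratum
    weights.
    """

    years: np.ndarray
    scenario: str
    seed: int
    incident: np.ndarray
    prevalent: np.ndarray
    cost: np.ndarray
    headcount: np.ndarray
    weights: np.ndarray
    incident_scaled: np.ndarray = field(init=False)
    prevalent_scaled: np.ndarray = field(init=False)
    cost_scaled: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        w = self.weights[..., None]
        self.incident_scaled = self.incident * w
        self.prevalent_scaled = self.prevalent * w
        self.cost_scaled = self.cost * w


@dataclass
class AttributableResult:
    """Baseline-minus-counterfactual outcomes with Monte Carlo half-widths.

    Mean arrays are averaged over replicates; ``*_reps`` keep the full
    per-replicate stacks (shape ``(R, ...)``) so any derived aggregate can
    carry an honest half-width. Half-width arrays are ``None`` for a single
    replicate.
    """

    years: np.ndarray
    incident_reps: np.ndarray
    prevalent_reps: np.ndarray
    cost_reps: np.ndarray

    @property
    def n_replicates(self) -> int:
        return self.incident_reps.shape[0]

    @property
    def incident(self) -> np.ndarray:
        return self.incident_reps.mean(axis=0)

    @property
    def prevalent(self) -> np.ndarray:
        return self.prevalent_reps.mean(axis=0)

    @property
    def cost(self) -> np.ndarray:
        return self.cost_reps.mean(axis=0)

    def half_width(self, measure: str = "incident") -> np.ndarray | None:
        """Per-cell Monte Carlo half-width, 1.96 * SD / sqrt(R)."""
        reps = getattr(self, f"{measure}_reps")
        r = reps.shape[0]
        if r < 2:
            return None
        return 1.96 * reps.std(axis=0, ddof=1) / np.sqrt(r)

    @property
    def incident_hw(self) -> np.ndarray | None:
        return self.half_width("incident")

    @property
    def cost_hw(self) -> np.ndarray | None:
        return self.half_width("cost")


def prepare_trend_model(bundle: InputBundle, config: SimulationConfig) -> CategoryTrendModel:
    """Fit the BMI-category trend once for reuse across scenario runs."""
    return fit_category_trend(
        bundle.surveys, form=config.functional_form, floor=config.logodds_floor
    )


def _baseline_probability_grid(
    model: CategoryTrendModel, years: np.ndarray
) -> np.ndarray:
    """Baseline category probabilities, shape (n_years, 2, n_rep_bands, 3).

    A reporting band without its own fitted stratum borrows the nearest
    fitted band of the same sex (cohorts ageing past the surveyed range keep
    a plausible category distribution).
    """
    fitted = {s: [b for (sx, b) in model.fits if sx == s] for s in SEXES}
    grid = np.empty((len(years), 2, N_REPORTING_BANDS, 3))
    for si, sex in enumerate(SEXES):
        if not fitted[sex]:
            raise CoverageError(f"no fitted BMI trend strata for sex {sex!r}")
        fitted_idx = sorted(REPORTING_BANDS.index(b) for b in fitted[sex] if b in REPORTING_BANDS)
        if not fitted_idx:
            raise CoverageError(
                f"no fitted BMI trend in the reporting age range for sex {sex!r}"
            )
        for bi, band in enumerate(REPORTING_BANDS):
            if (sex, band) in model.fits:
                src = band
            else:
                nearest = min(fitted_idx, key=lambda j: abs(j - bi))
                src = REPORTING_BANDS[nearest]
            for yi, year in enumerate(years):
                grid[yi, si, bi] = model.predict(sex, src, float(year))
    return grid


def _hazard_probability_grid(
    bundle: InputBundle, baseline_probs: np.ndarray, years: np.ndarray
) -> np.ndarray:
    """Annual contraction probabilities per category.

    Shape ``(n_diseases, n_years, 2, n_rep_bands, 3)``. The partition uses
    the baseline category mix in every scenario, keeping the
    population-average hazard calibrated to the input incidence.
    """
    out = np.zeros((N_DISEASES, len(years), 2, N_REPORTING_BANDS, 3))
    for di, disease in enumerate(DISEASES):
        inc = bundle.rates.reporting_array(disease, "incidence", default=0.0)
        rr = bundle.relative_risks.vector(disease)
        for yi in range(len(years)):
            for si in range(2):
                for bi in range(N_REPORTING_BANDS):
                    lam = partition_incidence(inc[si, bi], baseline_probs[yi, si, bi], rr)
                    out[di, yi, si, bi] = annual_probability(lam)
    return out


def _case_fatality_grid(bundle: InputBundle, config: SimulationConfig) -> np.ndarray:
    """Annual per-case death probabilities, shape (n_diseases, 2, n_rep_bands).

    T2DM carries no excess mortality. Chronic liver disease uses
    mortality / prevalence. Liver cancer has no prevalence input; its
    prevalent pool is approximated as incidence x mean survival
    (``cancer_survival_years``), giving fatality mortality / (incidence x s).
    """
    out = np.zeros((N_DISEASES, 2, N_REPORTING_BANDS))
    mort = bundle.rates.reporting_array("chronic_liver_disease", "mortality", default=0.0)
    prev = bundle.rates.reporting_array("chronic_liver_disease", "prevalence", default=0.0)
    for si in range(2):
        for bi in range(N_REPORTING_BANDS):
            if mort[si, bi] > 0 and prev[si, bi] == 0:
                raise ConfigurationError(
                    "chronic liver disease mortality without prevalence in stratum "
                    f"({SEXES[si]}, {REPORTING_BANDS[bi]})"
                )
            if mort[si, bi] > 0:
                out[CLD, si, bi] = derive_case_fatality(mort[si, bi], prev[si, bi])
    cmort = bundle.rates.reporting_array("liver_cancer", "mortality", default=0.0)
    cinc = bundle.rates.reporting_array("liver_cancer", "incidence", default=0.0)
    s = config.cancer_survival_years
    for si in range(2):
        for bi in range(N_REPORTING_BANDS):
            if cmort[si, bi] > 0 and cinc[si, bi] == 0:
                raise ConfigurationError(
                    "liver cancer mortality without incidence in stratum "
                    f"({SEXES[si]}, {REPORTING_BANDS[bi]})"
                )
            if cmort[si, bi] > 0:
                out[LIVER_CANCER, si, bi] = derive_case_fatality(cmort[si, bi], cinc[si, bi] * s)
    return out


def _stratum_sums(
    values: np.ndarray, sex: np.ndarray, rep_band: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Sum per (sex, reporting band) of ``values`` over ``mask`` -> (2, n_bands)."""
    idx = rep_band[mask] + N_REPORTING_BANDS * sex[mask]
    flat = np.bincount(idx, weights=values[mask], minlength=2 * N_REPORTING_BANDS)
    return flat.reshape(2, N_REPORTING_BANDS)


def run_scenario(
    config: SimulationConfig,
    bundle: InputBundle,
    replicate_seed: int,
    scenario: str | None = None,
    trend_model: CategoryTrendModel | None = None,
) -> ScenarioResult:
    """Execute one scenario run and return stratified, rescaled tallies."""
    scenario = scenario or config.scenario
    if scenario not in SCENARIOS:
        raise ConfigurationError(f"unknown scenario {scenario!r}")
    years = config.years
    ny = len(years)

    model = trend_model or prepare_trend_model(bundle, config)
    p_base = _baseline_probability_grid(model, years)
    hazprob = _hazard_probability_grid(bundle, p_base, years)
    fatality = _case_fatality_grid(bundle, config)

    if scenario == "counterfactual":
        p_assign = np.zeros_like(p_base)
        p_assign[..., 0] = 1.0
    else:
        p_assign = p_base

    salt = 0 if (config.use_common_random_numbers or scenario == "baseline") else 1
    streams = RandomStreams(replicate_seed, salt=salt)
    pop = build_initial_population(
        bundle.demography, config.n_sim, seed=replicate_seed, start_year=config.start_year
    )

    incident = np.zeros((ny, 2, N_REPORTING_BANDS, N_DISEASES))
    prevalent = np.zeros_like(incident)
    cost = np.zeros_like(incident)
    headcount = np.zeros((ny, 2, N_REPORTING_BANDS))

    for yi, year in enumerate(years):
        year = int(year)
        annual_vital_update(pop, bundle.demography, year, streams)
        n = pop.size
        sex = pop.sex
        bands = AGE_TO_BAND[pop.ages(year)]
        in_rep = (bands >= _FIRST_REP_BAND) & (bands <= _LAST_REP_BAND)
        # individuals past the surveyed range keep the oldest band's mix;
        # children are healthy by construction
        rep_band = np.clip(bands, _FIRST_REP_BAND, _LAST_REP_BAND) - _FIRST_REP_BAND

        # --- BMI category assignment (rank-preserving quantiles) ---
        t1 = p_assign[yi, sex, rep_band, 0]
        t2 = t1 + p_assign[yi, sex, rep_band, 1]
        cat = (pop.bmi_rank >= t1).astype(np.int8) + (pop.bmi_rank >= t2).astype(np.int8)
        cat[bands < _FIRST_REP_BAND] = 0
        pop.category = cat

        # --- disease contraction ---
        probs = np.zeros((N_DISEASES, n))
        for di in range(N_DISEASES):
            probs[di] = np.where(in_rep, hazprob[di, yi, sex, rep_band, cat], 0.0)
        u = np.stack(
            [streams.uniforms(year, f"contract_{d}", n) for d in DISEASES]
        )
        new = contract_diseases(pop, year, probs, u)
        for di in range(N_DISEASES):
            incident[yi, :, :, di] = _stratum_sums(
                np.ones(n), sex, rep_band, new[di] & in_rep
            )

        # --- disease deaths (chronic liver disease, liver cancer) ---
        for di, disease in ((CLD, DISEASES[CLD]), (LIVER_CANCER, DISEASES[LIVER_CANCER])):
            pcase = np.where(in_rep, fatality[di, sex, rep_band], 0.0)
            if pcase.any():
                ud = streams.uniforms(year, f"death_{disease}", n)
                apply_case_fatality(pop, year, disease, pcase, ud)

        # --- cost accrual ---
        inc_cost = accrue_annual_costs(pop, year, bundle.costs)
        for di in range(N_DISEASES):
            cost[yi, :, :, di] = _stratum_sums(inc_cost[:, di], sex, rep_band, in_rep)

        # --- end-of-year state tallies ---
        headcount[yi] = _stratum_sums(np.ones(n), sex, rep_band, pop.alive & in_rep)
        for di in range(N_DISEASES):
            prev_mask = pop.alive & in_rep & pop.has_disease(di)
            prevalent[yi, :, :, di] = _stratum_sums(np.ones(n), sex, rep_band, prev_mask)

    projected = bundle.demography.projected_array(years)
    weights = scaling_weights(headcount, projected, years).weights
    return ScenarioResult(
        years=years,
        scenario=scenario,
        seed=replicate_seed,
        incident=incident,
        prevalent=prevalent,
        cost=cost,
        headcount=headcount,
        weights=weights,
    )


def run_attributable_pair(
    config: SimulationConfig,
    bundle: InputBundle,
    replicate_seed: int,
    trend_model: CategoryTrendModel | None = None,
) -> AttributableResult:
    """Run baseline and zero-obesity counterfactual and difference them.

    With common random numbers (the default) both runs share every uniform
    draw keyed by (individual, year, purpose).
    """
    model = trend_model or prepare_trend_model(bundle, config)
    base = run_scenario(config, bundle, replicate_seed, "baseline", model)
    cf = run_scenario(config, bundle, replicate_seed, "counterfactual", model)
    return AttributableResult(
        years=config.years,
        incident_reps=(base.incident_scaled - cf.incident_scaled)[None],
        prevalent_reps=(base.prevalent_scaled - cf.prevalent_scaled)[None],
        cost_reps=(base.cost_scaled - cf.cost_scaled)[None],
    )


def replicate_and_error(
    config: SimulationConfig,
    bundle: InputBundle,
    trend_model: CategoryTrendModel | None = None,
) -> AttributableResult:
    """Replicate the attributable pair and attach Monte Carlo half-widths."""
    if config.n_replicates < 2:
        raise ValueError(
            "n_replicates must be >= 2 to estimate Monte Carlo error"
        )
    model = trend_model or prepare_trend_model(bundle, config)
    seeds = spawn_replicate_seeds(config.seed, config.n_replicates)
    reps = [run_attributable_pair(config, bundle, s, model) for s in seeds]
    return AttributableResult(
        years=config.years,
        incident_reps=np.concatenate([r.incident_reps for r in reps]),
        prevalent_reps=np.concatenate([r.prevalent_reps for r in reps]),
        cost_reps=np.concatenate([r.cost_reps for r in reps]),
    )
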