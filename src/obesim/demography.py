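"""Dynamic simulated population: initialisation, births, background deaths, rescaling.

The population is stored as a struct-of-arrays (:class:`Population`) so a run
with 10^5-10^6 individuals stays vectorised; :class:`Individual` is a
read-only per-person view used for inspection and small tests.

Conventions
-----------
* Single-year ages 0..100 are simulated internally; results are reported in
  five-year bands for ages 20-59. Simulating from birth lets cohorts flow
  into the reporting window over a 21-year horizon.
* ``age(year) = year - birth_year``; survivors therefore age by exactly one
  year per annual step.
* The population is closed except for births and deaths (no migration).
* Dead individuals are flagged, never removed, so cumulative tallies persist.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError
from .rng import RandomStreams
from .strata import (
    AGE_TO_BAND,
    FEMALE,
    MAX_AGE,
    N_DISEASES,
    N_REPORTING_BANDS,
    REPORTING_BAND_INDICES,
    SEXES,
    sex_index,
)

#: death-cause codes stored in ``Population.death_cause``
CAUSE_NONE = -1
CAUSE_BACKGROUND = 0
# disease-specific causes are 1 + disease index (1=t2dm unused, 2=CLD, 3=liver cancer)


@dataclass(frozen=True)
class Individual:
    """Read-only snapshot of one simulated person."""

    id: int
    sex: str
    birth_year: int
    alive: bool
    bmi_rank: float
    category: int
    onset_year: tuple[int, ...]  # per disease; -1 = never
    death_year: int
    death_cause: int
    cumulative_cost: tuple[float, ...]  # USD per disease


class Population:
    """Vectorised container for the simulated individuals.

    All arrays are index-aligned; index position is the individual id.
    """

    def __init__(self, sex: np.ndarray, birth_year: np.ndarray, bmi_rank: np.ndarray):
        n = len(sex)
        if not (len(birth_year) == len(bmi_rank) == n):
            raise ValueError("population arrays must have equal length")
        self.sex = np.asarray(sex, dtype=np.int8)
        self.birth_year = np.asarray(birth_year, dtype=np.int32)
        self.bmi_rank = np.asarray(bmi_rank, dtype=np.float64)
        self.alive = np.ones(n, dtype=bool)
        self.category = np.zeros(n, dtype=np.int8)
        self.onset_year = np.full((n, N_DISEASES), -1, dtype=np.int32)
        self.death_year = np.full(n, -1, dtype=np.int32)
        self.death_cause = np.full(n, CAUSE_NONE, dtype=np.int8)
        self.cost = np.zeros((n, N_DISEASES), dtype=np.float64)

    @property
    def size(self) -> int:
        return len(self.sex)

    def ages(self, year: int) -> np.ndarray:
        """Current single-year ages, capped at MAX_AGE."""
        return np.minimum(year - self.birth_year, MAX_AGE)

    def has_disease(self, disease_idx: int) -> np.ndarray:
        return self.onset_year[:, disease_idx] >= 0

    def n_alive(self) -> int:
        return int(self.alive.sum())

    def add_newborns(self, n: int, year: int, sex: np.ndarray, bmi_rank: np.ndarray) -> None:
        if n == 0:
            return
        self.sex = np.concatenate([self.sex, np.asarray(sex, dtype=np.int8)])
        self.birth_year = np.concatenate(
            [self.birth_year, np.full(n, year, dtype=np.int32)]
        )
        self.bmi_rank = np.concatenate([self.bmi_rank, np.asarray(bmi_rank, dtype=np.float64)])
        self.alive = np.concatenate([self.alive, np.ones(n, dtype=bool)])
        self.category = np.concatenate([self.category, np.zeros(n, dtype=np.int8)])
        self.onset_year = np.vstack(
            [self.onset_year, np.full((n, N_DISEASES), -1, dtype=np.int32)]
        )
        self.death_year = np.concatenate([self.death_year, np.full(n, -1, dtype=np.int32)])
        self.death_cause = np.concatenate(
            [self.death_cause, np.full(n, CAUSE_NONE, dtype=np.int8)]
        )
        self.cost = np.vstack([self.cost, np.zeros((n, N_DISEASES), dtype=np.float64)])

    def individual(self, i: int) -> Individual:
        return Individual(
            id=i,
            sex=SEXES[self.sex[i]],
            birth_year=int(self.birth_year[i]),
            alive=bool(self.alive[i]),
            bmi_rank=float(self.bmi_rank[i]),
            category=int(self.category[i]),
            onset_year=tuple(int(v) for v in self.onset_year[i]),
            death_year=int(self.death_year[i]),
            death_cause=int(self.death_cause[i]),
            cumulative_cost=tuple(float(v) for v in self.cost[i]),
        )


@dataclass
class DemographyInputs:
    """Demographic input tables.

    Attributes
    ----------
    pyramid:
        Initial population counts, columns ``sex, age, count`` (single-year ages).
    fertility:
        Births per woman-year by single-year maternal age, columns ``age, rate``.
    mortality:
        All-cause deaths per person-year, columns ``sex, age, rate``.
    projected:
        National projected headcount, columns ``year, sex, age_group, count``
        (five-year bands; at minimum the eight reporting bands for every
        simulated year).
    """

    pyramid: pd.DataFrame
    fertility: pd.DataFrame
    mortality: pd.DataFrame
    projected: pd.DataFrame
    # derived lookup arrays, built on validation
    mortality_array: np.ndarray = field(init=False, repr=False)
    fertility_array: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pyramid.empty:
            raise ConfigurationError("initial population pyramid is empty")
        for name, df, col in (
            ("pyramid", self.pyramid, "count"),
            ("projected", self.projected, "count"),
        ):
            if (df[col] < 0).any():
                raise ConfigurationError(f"{name} contains negative counts")
        for name, df in (("fertility", self.fertility), ("mortality", self.mortality)):
            bad = (df["rate"] < 0) | (df["rate"] > 1)
            if bad.any():
                raise ConfigurationError(
                    f"{name} rates must lie in [0, 1] per person-year"
                )
        # mortality lookup: NaN marks missing (sex, age) cells
        marr = np.full((2, MAX_AGE + 1), np.nan)
        for _, row in self.mortality.iterrows():
            marr[sex_index(row["sex"]), int(row["age"])] = float(row["rate"])
        self.mortality_array = marr
        farr = np.zeros(MAX_AGE + 1)
        for _, row in self.fertility.iterrows():
            farr[int(row["age"])] = float(row["rate"])
        self.fertility_array = farr

    def projected_array(self, years: np.ndarray) -> np.ndarray:
        """Projected headcount as ``(n_years, 2, n_reporting_bands)``.

        Raises :class:`CoverageError` if any (year, sex, reporting band) cell
        is missing.
        """
        from .strata import REPORTING_BANDS

        tab = self.projected.set_index(["year", "sex", "age_group"])["count"]
        out = np.empty((len(years), 2, N_REPORTING_BANDS))
        for yi, year in enumerate(years):
            for si, sex in enumerate(SEXES):
                for bi, band in enumerate(REPORTING_BANDS):
                    try:
                        out[yi, si, bi] = float(tab.loc[(int(year), sex, band)])
                    except KeyError:
                        raise CoverageError(
                            f"projected population missing ({year}, {sex}, {band})"
                        ) from None
        return out


def build_initial_population(
    inputs: DemographyInputs, n_sim: int, seed: int, start_year: int = 0
) -> Population:
    """Draw the starting population from the initial pyramid.

    Each individual's (sex, age) cell is drawn with probability equal to the
    cell's share of the pyramid mass; each individual receives an independent
    uniform BMI percentile rank in (0, 1). ``start_year`` anchors birth years
    so that ``age(start_year)`` equals the sampled pyramid age.
    """
    if n_sim < 1:
        raise ValueError(f"n_sim must be >= 1, got {n_sim}")
    pyramid = inputs.pyramid
    total = float(pyramid["count"].sum())
    if total <= 0:
        raise ConfigurationError("initial pyramid has zero total mass")
    rng = np.random.default_rng(seed)
    probs = pyramid["count"].to_numpy(dtype=float) / total
    cells = rng.choice(len(pyramid), size=n_sim, p=probs)
    sexes = pyramid["sex"].map(sex_index).to_numpy(dtype=np.int8)[cells]
    ages = pyramid["age"].to_numpy(dtype=np.int32)[cells]
    ranks = _open_unit_uniform(rng, n_sim)
    return Population(sex=sexes, birth_year=start_year - ages, bmi_rank=ranks)


def _open_unit_uniform(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniforms strictly inside (0, 1)."""
    u = rng.random(n)
    eps = np.finfo(float).tiny
    return np.clip(u, eps, 1.0 - np.finfo(float).epsneg)


def annual_vital_update(
    population: Population,
    inputs: DemographyInputs,
    year: int,
    rng: np.random.Generator | RandomStreams,
) -> Population:
    """One annual step of background deaths and births (in place).

    Every alive individual dies with the background all-cause probability for
    its (sex, age); survivors age implicitly by one year; newborns enter at
    age 0, one Bernoulli trial per alive woman at her age-specific fertility
    rate. Deaths are flagged, not removed.
    """
    n = population.size
    if isinstance(rng, RandomStreams):
        u_death = rng.uniforms(year, "mortality", n)
        u_birth = rng.uniforms(year, "births", n)
        newborn_rng = rng.generator(year, "newborn")
    else:
        u_death = rng.random(n)
        u_birth = rng.random(n)
        newborn_rng = rng

    ages = population.ages(year)
    alive = population.alive
    m = inputs.mortality_array[population.sex, ages]
    if np.isnan(m[alive]).any():
        bad = np.flatnonzero(alive & np.isnan(m))[0]
        raise CoverageError(
            "background mortality missing for alive individual stratum "
            f"({SEXES[population.sex[bad]]}, age {int(ages[bad])})"
        )
    dies = alive & (u_death < np.nan_to_num(m))
    population.alive[dies] = False
    population.death_year[dies] = year
    population.death_cause[dies] = CAUSE_BACKGROUND

    mothers = population.alive & (population.sex == FEMALE)
    f = inputs.fertility_array[ages]
    births = mothers & (u_birth < f)
    n_births = int(births.sum())
    if n_births:
        sexes = (newborn_rng.random(n_births) < 0.5).astype(np.int8)  # 50:50 sex ratio
        ranks = _open_unit_uniform(newborn_rng, n_births)
        population.add_newborns(n_births, year, sexes, ranks)
    return population


@dataclass(frozen=True)
class ScalingWeights:
    """Per-(year, sex, reporting band) factors mapping simulated to national counts."""

    years: np.ndarray
    weights: np.ndarray  # (n_years, 2, n_reporting_bands)


def scaling_weights(
    simulated_counts: np.ndarray, projected_counts: np.ndarray, years: np.ndarray
) -> ScalingWeights:
    """weight(y, s, a) = projected(y, s, a) / simulated(y, s, a).

    Applying the weights to simulated stratum headcounts recovers the
    projected stratum totals exactly. A stratum simulated empty while the
    projection expects people there is a coverage failure, reported with the
    offending stratum named.
    """
    from .strata import REPORTING_BANDS

    simulated = np.asarray(simulated_counts, dtype=float)
    projected = np.asarray(projected_counts, dtype=float)
    if simulated.shape != projected.shape:
        raise ValueError("simulated and projected count arrays must share a shape")
    bad = (simulated == 0) & (projected > 0)
    if bad.any():
        yi, si, bi = [int(v[0]) for v in np.nonzero(bad)]
        raise CoverageError(
            "no simulated individuals in stratum with nonzero projection: "
            f"({int(years[yi])}, {SEXES[si]}, {REPORTING_BANDS[bi]})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(simulated > 0, projected / np.where(simulated > 0, simulated, 1.0), 0.0)
    return ScalingWeights(years=np.asarray(years), weights=w)


def stratum_headcounts(population: Population, year: int) -> np.ndarray:
    """Alive headcount per (sex, reporting band) -> shape (2, n_reporting_bands)."""
    ages = population.ages(year)
    bands = AGE_TO_BAND[ages]
    out = np.zeros((2, N_REPORTING_BANDS))
    lo = REPORTING_BAND_INDICES[0]
    in_rep = population.alive & (bands >= lo) & (bands <= REPORTING_BAND_INDICES[-1])
    idx = (bands[in_rep] - lo) + N_REPORTING_BANDS * population.sex[in_rep]
    counts = np.bincount(idx, minlength=2 * N_REPORTING_BANDS)
    out[0, :] = counts[:N_REPORTING_BANDS]
    out[1, :] = counts[N_REPORTING_BANDS:]
    return out
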