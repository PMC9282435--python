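"""Per-BMI-category annual disease event probabilities.

The epidemiological inputs are population-level: overall incidence,
prevalence and mortality rates per (disease, sex, age band), plus relative
risks (RR) per BMI category with healthy weight as the reference. This
module converts them to the per-category hazards the simulation consumes.

Incidence partitioning
----------------------
With category probabilities ``p`` and relative risks ``rr`` (``rr[healthy]=1``),
the healthy-category incidence is ``lambda_h = I / (p . rr)`` and category
``c`` gets ``lambda_c = rr_c * lambda_h``. The probability-weighted mean then
equals the overall input incidence exactly, i.e. the model stays calibrated
to its source rates. Counterfactual runs keep the *baseline* partition (the
counterfactual changes who is exposed, not the per-category hazard).

Case fatality
-------------
The inputs carry population-level disease mortality, not per-case survival.
We derive an annual per-case death probability as
``1 - exp(-(mortality / prevalence))``: mortality/prevalence is the death
hazard among prevalent cases. T2DM carries no excess mortality here; chronic
liver disease and liver cancer do.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CoverageError, SchemaError
from .strata import (
    DISEASES,
    N_DISEASES,
    REPORTING_BANDS,
    SEXES,
    category_index,
    disease_index,
)

MEASURES = ("incidence", "prevalence", "mortality")
UNITS = ("per_100000", "per_person_year", "proportion")

_RATE_COLUMNS = ["disease", "measure", "sex", "age_group", "value", "units"]


class RateTable:
    """Disease epidemiology rates per (disease, measure, sex, age band).

    Built from a tidy frame with columns
    ``disease, measure, sex, age_group, value, units``; values are normalised
    internally to per person-year (rates) or proportions (prevalence).
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _RATE_COLUMNS if c not in frame.columns]
        if missing:
            raise SchemaError(f"rate table missing columns {missing}")
        self._rates: dict[tuple[str, str, str, str], float] = {}
        for _, row in frame.iterrows():
            disease, measure, units = row["disease"], row["measure"], row["units"]
            if disease not in DISEASES:
                raise SchemaError(f"unknown disease {disease!r} in rate table")
            if measure not in MEASURES:
                raise SchemaError(f"unknown measure {measure!r} in rate table")
            if units not in UNITS:
                raise SchemaError(f"unknown units {units!r} in rate table")
            value = float(row["value"])
            if value < 0:
                raise ConfigurationError(f"negative rate for {disease}/{measure}")
            if units == "per_100000":
                value = value / 1e5
            if measure == "prevalence" and not (0.0 <= value <= 1.0):
                raise ConfigurationError(
                    f"prevalence must be a proportion in [0,1], got {value}"
                )
            if measure in ("incidence", "mortality") and value >= 1.0:
                raise ConfigurationError(
                    f"{measure} of {value} per person-year is not a valid rate"
                )
            key = (disease, measure, row["sex"], str(row["age_group"]).strip())
            self._rates[key] = value

    def rate(self, disease: str, measure: str, sex: str, age_group: str) -> float:
        try:
            return self._rates[(disease, measure, sex, age_group)]
        except KeyError:
            raise CoverageError(
                f"no {measure} rate for ({disease}, {sex}, {age_group})"
            ) from None

    def has(self, disease: str, measure: str, sex: str, age_group: str) -> bool:
        return (disease, measure, sex, age_group) in self._rates

    def reporting_array(self, disease: str, measure: str, default: float = 0.0) -> np.ndarray:
        """Rates over the reporting strata, shape (2, n_reporting_bands).

        Strata absent from the table take ``default`` (no events there).
        """
        out = np.full((2, len(REPORTING_BANDS)), default, dtype=float)
        for si, sex in enumerate(SEXES):
            for bi, band in enumerate(REPORTING_BANDS):
                key = (disease, measure, sex, band)
                if key in self._rates:
                    out[si, bi] = self._rates[key]
        return out


@dataclass(frozen=True)
class RelativeRiskTable:
    """Relative risks per disease and BMI category, healthy = 1 reference.

    Odds ratios from the literature are used directly as RRs under the
    rare-disease assumption (incidence < 10%).
    """

    rr: dict[str, tuple[float, float, float]]  # disease -> (1, rr_pre, rr_obese)

    def __post_init__(self) -> None:
        for disease, vec in self.rr.items():
            if disease not in DISEASES:
                raise SchemaError(f"unknown disease {disease!r} in RR table")
            v = np.asarray(vec, dtype=float)
            if v.shape != (3,):
                raise SchemaError(f"RR vector for {disease} must have 3 entries")
            if v[0] != 1.0:
                raise ConfigurationError(
                    f"RR for the healthy reference category must be 1, got {v[0]}"
                )
            if (v < 0).any():
                raise ConfigurationError(f"negative RR for {disease}")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "RelativeRiskTable":
        """Build from a tidy frame with columns ``disease, category, rr``."""
        for col in ("disease", "category", "rr"):
            if col not in frame.columns:
                raise SchemaError(f"RR table missing column {col!r}")
        rr: dict[str, list[float]] = {}
        for _, row in frame.iterrows():
            d = row["disease"]
            rr.setdefault(d, [np.nan, np.nan, np.nan])[category_index(row["category"])] = float(row["rr"])
        out = {}
        for d, vec in rr.items():
            if np.isnan(vec).any():
                missing = [c for c, v in zip(("healthy", "pre_obese", "obese"), vec) if np.isnan(v)]
                raise SchemaError(f"RR table for {d} missing categories {missing}")
            out[d] = tuple(vec)
        return cls(out)

    def vector(self, disease: str) -> np.ndarray:
        try:
            return np.asarray(self.rr[disease], dtype=float)
        except KeyError:
            raise CoverageError(f"no relative risks for disease {disease!r}") from None


def partition_incidence(
    incidence: float, probabilities: np.ndarray, rr: np.ndarray
) -> np.ndarray:
    """Split an overall incidence rate into per-category hazards.

    Returns ``(lambda_healthy, lambda_pre, lambda_obese)`` with
    ``lambda_healthy = I / (p . rr)`` and ``lambda_c = rr_c * lambda_healthy``,
    so that ``sum_c p_c lambda_c == I`` exactly.
    """
    if incidence < 0:
        raise ValueError(f"incidence must be >= 0, got {incidence}")
    p = np.asarray(probabilities, dtype=float)
    r = np.asarray(rr, dtype=float)
    if p.shape != (3,) or r.shape != (3,):
        raise ValueError("probabilities and rr must be 3-vectors")
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must be a simplex 3-vector")
    if r[0] != 1.0:
        raise ValueError("rr must have the healthy reference equal to 1")
    if incidence == 0.0:
        return np.zeros(3)
    mean_rr = float(p @ r)
    if mean_rr == 0.0:
        raise ValueError(
            "degenerate input: p . rr = 0 with positive incidence cannot be partitioned"
        )
    lam_h = incidence / mean_rr
    return lam_h * r


def annual_probability(rate: float | np.ndarray) -> float | np.ndarray:
    """Convert a constant hazard (per person-year) to an annual risk.

    ``p = 1 - exp(-rate)``; lies in [0, 1) and is monotone in the rate.
    """
    rate_arr = np.asarray(rate, dtype=float)
    if (rate_arr < 0).any():
        raise ValueError("rate must be non-negative")
    out = -np.expm1(-rate_arr)
    return float(out) if np.isscalar(rate) or rate_arr.ndim == 0 else out


def derive_case_fatality(mortality: float, prevalence: float) -> float:
    """Annual per-case death probability from population-level inputs.

    The death hazard among prevalent cases is ``mortality / prevalence``
    (population deaths per person-year divided by the prevalent fraction);
    the annual probability is ``1 - exp(-hazard)``.
    """
    if mortality < 0 or prevalence < 0:
        raise ValueError("mortality and prevalence must be non-negative")
    if mortality == 0.0:
        return 0.0
    if prevalence == 0.0:
        raise ValueError(
            "degenerate input: positive mortality with zero prevalence"
        )
    return float(annual_probability(mortality / prevalence))


def contract_diseases(
    population,
    year: int,
    probs: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Draw first onsets for every disease across the population (in place).

    Parameters
    ----------
    population:
        A :class:`~obesim.demography.Population`; onset years are recorded
        on it.
    probs:
        Annual contraction probabilities, shape ``(n_diseases, population.size)``
        (already category-, age- and sex-specific per individual).
    u:
        Uniform draws of the same shape (common-random-number coupling keys
        them by individual id and purpose).

    Returns
    -------
    numpy.ndarray of bool, shape ``(n_diseases, population.size)``
        Mask of new onsets this year. Diseases are absorbing: an individual
        already carrying a disease is never re-incident, and dead
        individuals acquire nothing.
    """
    probs = np.asarray(probs, dtype=float)
    u = np.asarray(u, dtype=float)
    if probs.shape != (N_DISEASES, population.size) or u.shape != probs.shape:
        raise ValueError("probs and u must have shape (n_diseases, population size)")
    new = np.zeros_like(u, dtype=bool)
    for d in range(N_DISEASES):
        eligible = population.alive & ~population.has_disease(d)
        onset = eligible & (u[d] < probs[d])
        population.onset_year[onset, d] = year
        new[d] = onset
    return new


def apply_case_fatality(
    population,
    year: int,
    disease: str,
    prob_per_case: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Kill prevalent cases of ``disease`` with per-individual probability.

    Returns the mask of deaths recorded this year (flagged, not removed).
    """
    d = disease_index(disease)
    at_risk = population.alive & population.has_disease(d)
    dies = at_risk & (u < prob_per_case)
    population.alive[dies] = False
    population.death_year[dies] = year
    population.death_cause[dies] = 1 + d
    return dies
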