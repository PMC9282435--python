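"""Shared stratification vocabulary: sexes, BMI categories, diseases, age bands.

All modules index strata through the integer codes defined here so that
population-level tallies can live in plain numpy arrays of shape
``(year, sex, band, ...)``.
"""
from __future__ import annotations

import numpy as np

SEXES: tuple[str, ...] = ("male", "female")
MALE, FEMALE = 0, 1

#: WHO adult BMI classes: healthy (<25 kg/m^2), pre-obese (25-29.99), obese (>=30).
CATEGORIES: tuple[str, ...] = ("healthy", "pre_obese", "obese")
HEALTHY, PRE_OBESE, OBESE = 0, 1, 2

DISEASES: tuple[str, ...] = ("t2dm", "chronic_liver_disease", "liver_cancer")
T2DM, CLD, LIVER_CANCER = 0, 1, 2
N_DISEASES = len(DISEASES)

#: Oldest single-year age simulated; survivors are held at this age.
MAX_AGE = 100

#: Five-year age bands 0-4 ... 90-94 plus the open-ended 95+ band.
AGE_BANDS: tuple[str, ...] = tuple(f"{lo}-{lo + 4}" for lo in range(0, 95, 5)) + ("95+",)
N_BANDS = len(AGE_BANDS)

#: The eight working-age bands results are reported for (ages 20-59).
REPORTING_BANDS: tuple[str, ...] = tuple(f"{lo}-{lo + 4}" for lo in range(20, 60, 5))
REPORTING_BAND_INDICES: tuple[int, ...] = tuple(range(4, 12))
N_REPORTING_BANDS = len(REPORTING_BANDS)
REPORTING_AGE_RANGE = (20, 59)

#: Lookup: single-year age (0..MAX_AGE) -> five-year band index.
AGE_TO_BAND: np.ndarray = np.minimum(np.arange(MAX_AGE + 1) // 5, N_BANDS - 1)


def sex_index(label: str) -> int:
    """Return the integer code for a sex label."""
    try:
        return SEXES.index(label)
    except ValueError:
        raise ValueError(f"unknown sex label {label!r}; expected one of {SEXES}") from None


def category_index(label: str) -> int:
    try:
        return CATEGORIES.index(label)
    except ValueError:
        raise ValueError(
            f"unknown BMI category {label!r}; expected one of {CATEGORIES}"
        ) from None


def disease_index(label: str) -> int:
    try:
        return DISEASES.index(label)
    except ValueError:
        raise ValueError(f"unknown disease {label!r}; expected one of {DISEASES}") from None


def parse_age_band(label: str) -> tuple[int, int]:
    """Parse an age-band label like ``"20-24"`` or ``"95+"`` into (low, high)."""
    label = str(label).strip()
    if label.endswith("+"):
        lo = int(label[:-1])
        return lo, MAX_AGE
    try:
        lo_s, hi_s = label.split("-")
        lo, hi = int(lo_s), int(hi_s)
    except ValueError:
        raise ValueError(f"cannot parse age band label {label!r}") from None
    if hi < lo:
        raise ValueError(f"inverted age band {label!r}")
    return lo, hi


def band_index(label: str) -> int:
    """Return the band index of a canonical five-year band label."""
    try:
        return AGE_BANDS.index(str(label).strip())
    except ValueError:
        raise ValueError(
            f"age band {label!r} is not one of the canonical five-year bands"
        ) from None
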