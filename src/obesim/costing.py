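"""Direct health care cost accrual.

T2DM and chronic liver disease carry an annual per-patient cost for every
prevalent case-year while the individual is alive; liver cancer carries a
single terminal cost attached to the year of death from liver cancer
(the source cost is defined over the last 12 months of life). Costs start in
the onset year (a full year — the model runs at annual resolution) and stop
at death. No discounting or inflation adjustment is applied over the
horizon; the currency-year label is carried through to outputs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .strata import CLD, LIVER_CANCER, N_DISEASES, T2DM


@dataclass(frozen=True)
class CostSchedule:
    """Unit costs in USD.

    Attributes
    ----------
    annual_cost_t2dm:
        Annual mean health care expenditure per patient with T2DM.
    annual_cost_cld:
        Annual mean health care expenditure per patient with chronic liver
        disease.
    terminal_cost_liver_cancer:
        Health care expenditure per liver-cancer patient over the last 12
        months of life, charged once in the year of death.
    currency_year:
        Label describing the price year of the cost constants.
    """

    annual_cost_t2dm: float
    annual_cost_cld: float
    terminal_cost_liver_cancer: float
    currency_year: str = "2010 USD"

    def __post_init__(self) -> None:
        for name in ("annual_cost_t2dm", "annual_cost_cld", "terminal_cost_liver_cancer"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"cost constant {name} must be >= 0")


def accrue_annual_costs(population, year: int, schedule: CostSchedule) -> np.ndarray:
    """Accrue this year's costs onto the population (in place).

    Returns the per-individual cost increments, shape
    ``(population.size, n_diseases)``, so callers can tally them by stratum.
    Alive prevalent T2DM and chronic-liver-disease cases accrue their annual
    unit cost; individuals whose recorded death this year was caused by
    liver cancer accrue the terminal cost exactly once.
    """
    inc = np.zeros((population.size, N_DISEASES))
    for d, unit in ((T2DM, schedule.annual_cost_t2dm), (CLD, schedule.annual_cost_cld)):
        prevalent = (
            population.alive
            & population.has_disease(d)
            & (population.onset_year[:, d] <= year)
        )
        inc[prevalent, d] = unit
    cancer_death = (population.death_year == year) & (
        population.death_cause == 1 + LIVER_CANCER
    )
    inc[cancer_death, LIVER_CANCER] = schedule.terminal_cost_liver_cancer
    population.cost += inc
    return inc
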