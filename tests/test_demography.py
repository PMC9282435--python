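"""Population initialisation, vital dynamics and rescaling weights."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from obesim import (
    ConfigurationError,
    CoverageError,
    DemographyInputs,
    annual_vital_update,
    build_initial_population,
    scaling_weights,
    stratum_headcounts,
)
from obesim.strata import MALE, MAX_AGE, SEXES


def _inputs(pyramid_rows, mortality_rate=0.0, fertility_rate=0.0):
    ages = np.arange(MAX_AGE + 1)
    return DemographyInputs(
        pyramid=pd.DataFrame(pyramid_rows, columns=["sex", "age", "count"]),
        fertility=pd.DataFrame({"age": ages, "rate": np.where(
            (ages >= 15) & (ages < 50), fertility_rate, 0.0)}),
        mortality=pd.DataFrame(
            [(s, int(a), mortality_rate) for s in SEXES for a in ages],
            columns=["sex", "age", "rate"],
        ),
        projected=pd.DataFrame(columns=["year", "sex", "age_group", "count"]),
    )


class TestBuildInitialPopulation:
    def test_degenerate_pyramid_is_reproduced_exactly(self):
        inputs = _inputs([("male", 30, 1.0)])
        pop = build_initial_population(inputs, n_sim=1000, seed=0, start_year=2020)
        assert pop.size == 1000
        assert (pop.sex == MALE).all()
        assert (pop.ages(2020) == 30).all()

    def test_even_pyramid_male_share_within_binomial_error(self):
        inputs = _inputs([("male", 30, 1.0), ("female", 30, 1.0)])
        n = 100_000
        pop = build_initial_population(inputs, n_sim=n, seed=7)
        share = (pop.sex == MALE).mean()
        se = np.sqrt(0.25 / n)
        assert abs(share - 0.5) < 3 * se

    def test_ranks_lie_in_open_unit_interval(self):
        inputs = _inputs([("female", 40, 2.0)])
        pop = build_initial_population(inputs, n_sim=5000, seed=3)
        assert (pop.bmi_rank > 0).all() and (pop.bmi_rank < 1).all()

    def test_invalid_arguments(self):
        inputs = _inputs([("male", 30, 1.0)])
        with pytest.raises(ValueError):
            build_initial_population(inputs, n_sim=0, seed=0)
        with pytest.raises(ConfigurationError):
            _inputs([])


class TestAnnualVitalUpdate:
    def test_null_rates_leave_population_invariant_apart_from_aging(self):
        inputs = _inputs([("male", 30, 1.0), ("female", 20, 1.0)])
        pop = build_initial_population(inputs, n_sim=2000, seed=0, start_year=2020)
        ages_before = pop.ages(2020).copy()
        annual_vital_update(pop, inputs, 2021, np.random.default_rng(0))
        assert pop.size == 2000
        assert pop.alive.all()
        np.testing.assert_array_equal(pop.ages(2021), ages_before + 1)

    def test_certain_death_kills_everyone(self):
        inputs = _inputs([("male", 50, 1.0)], mortality_rate=1.0)
        pop = build_initial_population(inputs, n_sim=500, seed=0, start_year=2020)
        annual_vital_update(pop, inputs, 2020, np.random.default_rng(1))
        assert not pop.alive.any()
        assert (pop.death_year == 2020).all()

    def test_death_count_matches_binomial_oracle(self):
        inputs = _inputs([("male", 40, 1.0)], mortality_rate=0.01)
        n = 100_000
        pop = build_initial_population(inputs, n_sim=n, seed=0, start_year=2020)
        annual_vital_update(pop, inputs, 2020, np.random.default_rng(5))
        deaths = n - pop.n_alive()
        se = np.sqrt(n * 0.01 * 0.99)
        assert abs(deaths - n * 0.01) < 3 * se

    def test_population_size_is_conserved_every_step(self):
        inputs = _inputs(
            [("female", 25, 1.0), ("male", 25, 1.0)],
            mortality_rate=0.02, fertility_rate=0.1,
        )
        pop = build_initial_population(inputs, n_sim=20_000, seed=2, start_year=2020)
        rng = np.random.default_rng(9)
        for year in range(2020, 2026):
            alive_before = pop.n_alive()
            size_before = pop.size
            annual_vital_update(pop, inputs, year, rng)
            births = pop.size - size_before
            deaths = int(((pop.death_year == year)).sum())
            assert pop.n_alive() == alive_before - deaths + births

    def test_deaths_are_flagged_not_removed(self):
        inputs = _inputs([("male", 40, 1.0)], mortality_rate=0.5)
        pop = build_initial_population(inputs, n_sim=1000, seed=0, start_year=2020)
        annual_vital_update(pop, inputs, 2020, np.random.default_rng(0))
        assert pop.size == 1000
        assert 0 < pop.n_alive() < 1000

    def test_missing_mortality_rate_raises_coverage_error(self):
        inputs = _inputs([("male", 40, 1.0)])
        inputs.mortality_array[MALE, 40] = np.nan
        pop = build_initial_population(inputs, n_sim=10, seed=0, start_year=2020)
        with pytest.raises(CoverageError, match="male"):
            annual_vital_update(pop, inputs, 2020, np.random.default_rng(0))


class TestScalingWeights:
    def test_simple_division(self):
        years = np.array([2020])
        sim = np.full((1, 2, 8), 5_000.0)
        proj = np.full((1, 2, 8), 2_000_000.0)
        w = scaling_weights(sim, proj, years).weights
        assert (w == 400.0).all()

    def test_identity_when_simulated_equals_projected(self):
        years = np.array([2020, 2021])
        sim = np.random.default_rng(0).uniform(10, 100, (2, 2, 8))
        w = scaling_weights(sim, sim.copy(), years).weights
        np.testing.assert_allclose(w, 1.0, rtol=1e-12)

    def test_weights_recover_projected_totals_exactly(self):
        rng = np.random.default_rng(4)
        years = np.array([2020])
        sim = rng.integers(100, 1000, (1, 2, 8)).astype(float)
        proj = rng.uniform(1e5, 1e6, (1, 2, 8))
        w = scaling_weights(sim, proj, years).weights
        np.testing.assert_allclose(sim * w, proj, rtol=1e-12)

    def test_empty_stratum_with_projection_names_the_stratum(self):
        years = np.array([2020])
        sim = np.ones((1, 2, 8))
        sim[0, 1, 3] = 0.0
        proj = np.ones((1, 2, 8))
        with pytest.raises(CoverageError, match=r"female.*35-39"):
            scaling_weights(sim, proj, years)


def test_stratum_headcounts_counts_only_alive_reporting_ages():
    inputs = _inputs([("male", 30, 1.0), ("female", 70, 1.0), ("male", 10, 1.0)])
    pop = build_initial_population(inputs, n_sim=30_000, seed=0, start_year=2020)
    counts = stratum_headcounts(pop, 2020)
    # only the male 30-34 stratum lies in the reporting window
    assert counts[0].sum() == (pop.ages(2020) == 30).sum()
    assert counts[1].sum() == 0
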