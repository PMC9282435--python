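"""Incidence partitioning, rate-to-risk conversion, case fatality, contraction."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obesim import (
    ConfigurationError,
    Population,
    RateTable,
    RelativeRiskTable,
    annual_probability,
    contract_diseases,
    derive_case_fatality,
    partition_incidence,
)
from obesim.disease_model import apply_case_fatality
from obesim.strata import CLD, N_DISEASES, T2DM


def _small_population(n=10, age=40):
    return Population(
        sex=np.zeros(n, dtype=np.int8),
        birth_year=np.full(n, 2020 - age),
        bmi_rank=np.full(n, 0.5),
    )


class TestPartitionIncidence:
    def test_worked_partition(self):
        lam = partition_incidence(0.01, np.array([0.4, 0.4, 0.2]), np.array([1, 1.5, 3.0]))
        np.testing.assert_allclose(lam, [0.00625, 0.009375, 0.01875], rtol=1e-12)

    def test_null_relative_risks_give_uniform_hazard(self):
        lam = partition_incidence(0.02, np.array([0.3, 0.3, 0.4]), np.ones(3))
        np.testing.assert_allclose(lam, 0.02, rtol=1e-12)

    def test_zero_incidence(self):
        lam = partition_incidence(0.0, np.array([0.3, 0.3, 0.4]), np.array([1, 2, 3.0]))
        np.testing.assert_array_equal(lam, 0.0)

    def test_degenerate_exposure_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            partition_incidence(0.01, np.array([0.0, 0.0, 1.0]), np.array([1.0, 1.0, 0.0]))

    @given(
        i=st.floats(1e-6, 0.5),
        p1=st.floats(0.01, 0.98), p2=st.floats(0.01, 0.98),
        rp=st.floats(0.1, 10.0), ro=st.floats(0.1, 10.0),
    )
    def test_conservation_and_monotonicity(self, i, p1, p2, rp, ro):
        """The category mix always averages back to the input incidence."""
        if p1 + p2 >= 0.99:
            return
        p = np.array([p1, p2, 1.0 - p1 - p2])
        rr = np.array([1.0, rp, ro])
        lam = partition_incidence(i, p, rr)
        assert p @ lam == pytest.approx(i, rel=1e-12)
        if 1.0 <= rp <= ro:
            assert lam[0] <= lam[1] <= lam[2]


class TestAnnualProbability:
    def test_closed_form_values(self):
        assert annual_probability(0.0) == 0.0
        assert annual_probability(0.00625) == pytest.approx(1 - np.exp(-0.00625), rel=1e-12)

    def test_monotone_and_bounded(self):
        rates = np.linspace(0, 5, 50)
        p = annual_probability(rates)
        assert (np.diff(p) > 0).all()
        assert (p >= 0).all() and (p < 1).all()

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            annual_probability(-0.1)


class TestCaseFatality:
    def test_population_level_worked_example(self):
        # mortality 1.2 and prevalence 500 per 100,000 => hazard 0.0024 per case-year
        f = derive_case_fatality(1.2e-5, 500e-5)
        assert f == pytest.approx(1 - np.exp(-0.0024), rel=1e-12)

    def test_zero_mortality_gives_zero(self):
        assert derive_case_fatality(0.0, 0.0) == 0.0

    def test_monotone_in_mortality(self):
        fs = [derive_case_fatality(m, 0.005) for m in (1e-5, 2e-5, 4e-5)]
        assert fs[0] < fs[1] < fs[2]

    def test_mortality_without_prevalence_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            derive_case_fatality(1e-5, 0.0)


class TestContractDiseases:
    def test_null_hazards_change_nothing(self):
        pop = _small_population(100)
        probs = np.zeros((N_DISEASES, 100))
        u = np.random.default_rng(0).random((N_DISEASES, 100))
        new = contract_diseases(pop, 2020, probs, u)
        assert not new.any()
        assert (pop.onset_year == -1).all()

    def test_near_certain_contraction_matches_binomial_oracle(self):
        n = 10_000
        pop = _small_population(n)
        probs = np.full((N_DISEASES, n), 0.999)
        u = np.random.default_rng(1).random((N_DISEASES, n))
        new = contract_diseases(pop, 2020, probs, u)
        count = int(new[T2DM].sum())
        se = np.sqrt(n * 0.999 * 0.001)
        assert abs(count - n * 0.999) < 3 * se

    def test_disease_is_absorbing(self):
        """A prevalent case is never re-incident; first onset year persists."""
        n = 50
        pop = _small_population(n)
        probs = np.ones((N_DISEASES, n)) * 0.9999
        rng = np.random.default_rng(2)
        contract_diseases(pop, 2020, probs, rng.random((N_DISEASES, n)))
        onset_before = pop.onset_year.copy()
        new = contract_diseases(pop, 2021, probs, rng.random((N_DISEASES, n)))
        assert not (new & (onset_before.T >= 0)).any()
        np.testing.assert_array_equal(
            pop.onset_year[onset_before >= 0], onset_before[onset_before >= 0]
        )

    def test_dead_individuals_acquire_nothing(self):
        n = 20
        pop = _small_population(n)
        pop.alive[:10] = False
        probs = np.ones((N_DISEASES, n))
        u = np.zeros((N_DISEASES, n))
        new = contract_diseases(pop, 2020, probs, u)
        assert not new[:, :10].any()
        assert new[:, 10:].all()


def test_apply_case_fatality_flags_disease_deaths():
    n = 100
    pop = _small_population(n)
    pop.onset_year[:50, CLD] = 2020
    dies = apply_case_fatality(
        pop, 2021, "chronic_liver_disease", np.ones(n), np.zeros(n)
    )
    assert dies.sum() == 50
    assert (pop.death_cause[:50] == 1 + CLD).all()
    assert (pop.death_year[:50] == 2021).all()
    assert pop.alive[50:].all()


class TestRateAndRRTables:
    def test_per_100k_normalisation(self):
        frame = pd.DataFrame(
            [["t2dm", "incidence", "male", "40-44", 500.0, "per_100000"]],
            columns=["disease", "measure", "sex", "age_group", "value", "units"],
        )
        table = RateTable(frame)
        assert table.rate("t2dm", "incidence", "male", "40-44") == pytest.approx(5e-3)

    def test_missing_reference_rr_rejected(self):
        frame = pd.DataFrame(
            [["t2dm", "pre_obese", 3.0], ["t2dm", "obese", 7.0]],
            columns=["disease", "category", "rr"],
        )
        from obesim import SchemaError

        with pytest.raises(SchemaError, match="healthy"):
            RelativeRiskTable.from_frame(frame)

    def test_non_unit_reference_rejected(self):
        with pytest.raises(ConfigurationError):
            RelativeRiskTable({"t2dm": (2.0, 3.0, 7.0)})
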