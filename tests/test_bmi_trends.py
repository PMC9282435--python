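"""BMI-category trend fitting, projection and rank-based assignment."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from obesim import (
    SurveyPoint,
    UnderDeterminedError,
    apply_counterfactual,
    assign_categories,
    assign_category,
    fit_category_trend,
    project_category_probabilities,
)
from obesim.bmi_trends import TIME_ORIGIN, _softmax3


def _points(data, sex="male", band="30-34", n=2000):
    return [
        SurveyPoint(year=y, sex=sex, age_group=band, proportions=p, n_sample=n)
        for y, p in data
    ]


def _truth_points(intercepts, slopes, years, sex="male", band="30-34", n=None, rng=None):
    """Survey points from known linear log-odds parameters."""
    pts = []
    for y in years:
        tau = y - TIME_ORIGIN
        p = _softmax3(intercepts[0] + slopes[0] * tau, intercepts[1] + slopes[1] * tau)
        if n is not None:
            p = rng.multinomial(n, p) / n
        pts.append(
            SurveyPoint(year=y, sex=sex, age_group=band,
                        proportions=tuple(p), n_sample=n or 10**9)
        )
    return pts


class TestFit:
    def test_constant_data_gives_zero_slopes_and_flat_projection(self):
        pts = _points([(2005, (0.4, 0.35, 0.25)), (2013, (0.4, 0.35, 0.25))])
        model = fit_category_trend(pts, form="linear")
        assert model.slope("male", "30-34", "pre_obese") == pytest.approx(0.0, abs=1e-8)
        assert model.slope("male", "30-34", "obese") == pytest.approx(0.0, abs=1e-8)
        p2040 = project_category_probabilities(model, "male", "30-34", 2040)
        np.testing.assert_allclose(p2040, (0.4, 0.35, 0.25), atol=1e-7)

    def test_two_point_linear_fit_is_saturated(self):
        """Free parameters == informative data points => exact reproduction."""
        data = [(2005, (0.5, 0.3, 0.2)), (2016, (0.35, 0.33, 0.32))]
        model = fit_category_trend(_points(data), form="linear")
        for year, props in data:
            fitted = model.predict("male", "30-34", year)
            np.testing.assert_allclose(fitted, props, atol=1e-7)

    def test_single_year_is_underdetermined(self):
        pts = _points([(2013, (0.4, 0.35, 0.25))])
        with pytest.raises(UnderDeterminedError):
            fit_category_trend(pts, form="linear")

    def test_saturating_form_needs_three_years(self):
        pts = _points([(2005, (0.4, 0.35, 0.25)), (2013, (0.4, 0.35, 0.25))])
        with pytest.raises(UnderDeterminedError):
            fit_category_trend(pts, form="saturating")

    def test_slope_recovery_from_noisy_surveys(self):
        rng = np.random.default_rng(11)
        slopes = (0.01, 0.03)
        pts = _truth_points((-0.2, -0.8), slopes, (2005, 2011, 2013, 2016),
                            n=50_000, rng=rng)
        model = fit_category_trend(pts, form="linear")
        assert model.slope("male", "30-34", "pre_obese") == pytest.approx(0.01, abs=0.01)
        assert model.slope("male", "30-34", "obese") == pytest.approx(0.03, abs=0.01)
        lo, hi = model.slope_interval("male", "30-34", "obese")
        assert lo < hi

    def test_degenerate_category_pinned_at_floor_with_warning(self):
        pts = _points([(2005, (0.6, 0.4, 0.0)), (2013, (0.5, 0.5, 0.0))])
        with pytest.warns(UserWarning, match="obese"):
            model = fit_category_trend(pts, form="linear")
        p = model.predict("male", "30-34", 2030)
        assert p[2] < 1e-8
        np.testing.assert_allclose(p.sum(), 1.0, rtol=1e-12)


class TestProjection:
    def test_projection_is_a_simplex_at_any_year(self):
        pts = _points([(2005, (0.5, 0.3, 0.2)), (2016, (0.35, 0.33, 0.32))])
        model = fit_category_trend(pts, form="linear")
        for year in (1990, 2020, 2040, 2100):
            p = model.predict("male", "30-34", year)
            assert (p > 0).all() and (p < 1).all()
            np.testing.assert_allclose(p.sum(), 1.0, rtol=1e-12)

    def test_linear_form_is_linear_on_log_odds(self):
        """Projection at the midpoint year equals the log-odds midpoint of flanking years."""
        pts = _points([(2005, (0.5, 0.3, 0.2)), (2016, (0.35, 0.33, 0.32))])
        model = fit_category_trend(pts, form="linear")

        def logodds(year):
            p = model.predict("male", "30-34", year)
            return np.log(p[1:] / p[0])

        mid = logodds(2030)
        flank = 0.5 * (logodds(2020) + logodds(2040))
        np.testing.assert_allclose(mid, flank, rtol=1e-9, atol=1e-12)

    def test_unfitted_stratum_raises_coverage_error(self):
        from obesim import CoverageError

        pts = _points([(2005, (0.4, 0.35, 0.25)), (2013, (0.4, 0.35, 0.25))])
        model = fit_category_trend(pts, form="linear")
        with pytest.raises(CoverageError):
            model.predict("female", "30-34", 2030)


class TestCounterfactual:
    @pytest.mark.parametrize(
        "probs", [(0.3, 0.4, 0.3), (1.0, 0.0, 0.0), (0.2, 0.5, 0.3)]
    )
    def test_everyone_healthy(self, probs):
        out = apply_counterfactual(np.array(probs))
        np.testing.assert_array_equal(out, (1.0, 0.0, 0.0))

    def test_rejects_non_simplex_input(self):
        with pytest.raises(ValueError):
            apply_counterfactual(np.array([0.5, 0.2, 0.2]))


class TestAssignment:
    def test_quantile_rule(self):
        p = np.array([0.4, 0.4, 0.2])
        assert assign_category(0.10, p) == 0
        assert assign_category(0.50, p) == 1
        assert assign_category(0.95, p) == 2

    def test_rank_bounds_enforced(self):
        p = np.array([0.4, 0.4, 0.2])
        for bad in (0.0, 1.0, -0.2, 1.7):
            with pytest.raises(ValueError):
                assign_category(bad, p)

    def test_population_shares_match_multinomial_oracle(self):
        rng = np.random.default_rng(21)
        n = 100_000
        ranks = rng.random(n).clip(1e-12, 1 - 1e-12)
        p = np.array([0.35, 0.4, 0.25])
        cats = assign_categories(ranks, p)
        for c in range(3):
            share = (cats == c).mean()
            se = np.sqrt(p[c] * (1 - p[c]) / n)
            assert abs(share - p[c]) < 3 * se

    @given(
        r1=st.floats(0.001, 0.999), r2=st.floats(0.001, 0.999),
        ph=st.floats(0.05, 0.9), pp=st.floats(0.05, 0.9),
    )
    def test_assignment_is_monotone_in_rank(self, r1, r2, ph, pp):
        if ph + pp >= 0.999:
            return
        p = np.array([ph, pp, 1.0 - ph - pp])
        lo, hi = sorted((r1, r2))
        assert assign_category(lo, p) <= assign_category(hi, p)
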