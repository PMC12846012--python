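"""Regression, Emission Control Threshold, exceedance and permit screening."""

import numpy as np
import pandas as pd
import pytest

from firepm25.aggregate import DailySeries
from firepm25.analytics import (
    EmissionUnit,
    RegressionResult,
    classify_days,
    fit_ols,
    invert_threshold,
    pearson_r,
    screen_request,
    spatial_corr,
)
from firepm25.errors import ArgumentError
from firepm25.landcover import FuelParameterTable
from firepm25.reference import (
    DEFAULT_Y_TARGET,
    REFERENCE_ALPHA,
    REFERENCE_BETA_PER_KG,
    reference_regression,
)


class TestPearson:
    def test_identity_is_one(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_negative_affine_is_minus_one(self):
        x = np.arange(10.0)
        assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self):
        rng = np.random.default_rng(123)
        x, y = rng.normal(size=10_000), rng.normal(size=10_000)
        assert abs(pearson_r(x, y)) < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(ArgumentError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestFitOls:
    def test_noiseless_exact_recovery(self):
        x = np.linspace(0, 100, 50)
        res = fit_ols(x, 2 + 3 * x)
        assert res.alpha == pytest.approx(2.0, abs=1e-9)
        assert res.beta == pytest.approx(3.0, abs=1e-12)
        assert res.r2 == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_zero_slope(self):
        x = np.linspace(0, 10, 20)
        res = fit_ols(x, np.full(20, 7.0))
        assert res.beta == pytest.approx(0.0, abs=1e-12)
        assert res.r2 == pytest.approx(0.0, abs=1e-12)

    def test_fit_on_own_fitted_values_is_perfect(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1e6, 121)
        y = 40.0 + 5e-6 * x + rng.normal(0, 10, 121)
        res = fit_ols(x, y)
        fitted = res.alpha + res.beta * x
        assert fit_ols(x, fitted).r2 == pytest.approx(1.0, abs=1e-9)

    def test_r_squared_equals_r_squared(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 50)
        y = 1 + 0.5 * x + rng.normal(0, 5, 50)
        res = fit_ols(x, y)
        assert res.r2 == pytest.approx(res.r**2, abs=1e-12)

    def test_parameter_recovery_within_confidence_intervals(self):
        """A season generated at the published coefficients is recovered
        within the fit's own 95% intervals (fixed seed)."""
        rng = np.random.default_rng(42)
        x_kg = rng.uniform(0, 14e6, 121)
        y = REFERENCE_ALPHA + REFERENCE_BETA_PER_KG * x_kg + rng.normal(0, 10, 121)
        res = fit_ols(x_kg, y, EmissionUnit.KG_PER_DAY)
        assert res.alpha_ci[0] <= REFERENCE_ALPHA <= res.alpha_ci[1]
        assert res.beta_ci[0] <= REFERENCE_BETA_PER_KG <= res.beta_ci[1]

    def test_too_short_or_constant_rejected(self):
        with pytest.raises(ArgumentError):
            fit_ols([1, 2], [1, 2])
        with pytest.raises(ArgumentError):
            fit_ols([3, 3, 3], [1, 2, 3])


class TestThresholdInversion:
    def test_published_coefficients_give_1518_tons(self):
        """(50 − 40.41)/0.00000631343 kg/day floors to the published
        Emission Control Threshold of 1518 tons/day."""
        th = invert_threshold(reference_regression(), DEFAULT_Y_TARGET)
        assert th.x_star == 1518.0

    def test_constructed_round_trip_in_kg(self):
        res = RegressionResult(
            alpha=40.0, beta=1e-5, r=0.7, r2=0.49, p=1e-6, n=100,
            x_unit=EmissionUnit.KG_PER_DAY,
        )
        th = invert_threshold(res, y_target=40.0 + 1e-5 * 1e6)
        assert th.x_star == 1000.0

    def test_tons_unit_needs_no_conversion(self):
        res = RegressionResult(
            alpha=10.0, beta=0.02, r=0.7, r2=0.49, p=1e-6, n=100,
            x_unit=EmissionUnit.TONS_PER_DAY,
        )
        th = invert_threshold(res, y_target=50.0)
        assert th.x_star == 2000.0

    def test_baseline_above_target_is_an_error(self):
        res = RegressionResult(
            alpha=51.0, beta=1e-5, r=0.7, r2=0.49, p=1e-6, n=100,
            x_unit=EmissionUnit.KG_PER_DAY,
        )
        with pytest.raises(ArgumentError, match="baseline exceeds target"):
            invert_threshold(res, y_target=50.0)

    @pytest.mark.parametrize("alpha,beta,y", [(40.41, 6.31343e-6, 50.0),
                                              (30.0, 2.5e-6, 45.0),
                                              (10.0, 9.9e-6, 50.0)])
    def test_floor_round_trip_bounds(self, alpha, beta, y):
        """At X* the prediction is at or below target; one more ton tips it
        above or touches it."""
        res = RegressionResult(alpha=alpha, beta=beta, r=0.7, r2=0.5, p=1e-9,
                               n=121, x_unit=EmissionUnit.KG_PER_DAY)
        th = invert_threshold(res, y)
        assert alpha + beta * th.x_star * 1000 <= y + 1e-9
        assert alpha + beta * (th.x_star + 1) * 1000 > y - 1e-9


class TestClassifyDays:
    def make_series(self, values, start="2024-03-01"):
        idx = pd.date_range(start, periods=len(values), freq="D")
        return DailySeries(pd.Series(values, index=idx, dtype=float))

    def threshold(self, x_star):
        return invert_threshold(
            RegressionResult(alpha=0.0, beta=1.0, r=1, r2=1, p=0, n=10,
                             x_unit=EmissionUnit.TONS_PER_DAY),
            y_target=float(x_star),
        )

    def test_exactly_at_threshold_is_within(self):
        out = classify_days(self.make_series([1518.0]), self.threshold(1518))
        assert out["n_exceed"] == 0

    def test_extreme_day_exceeds(self):
        out = classify_days(self.make_series([10_000.0]), self.threshold(1518))
        assert out["n_exceed"] == 1

    def test_all_zero_series_never_exceeds(self):
        out = classify_days(self.make_series([0.0] * 30), self.threshold(1518))
        assert out["n_exceed"] == 0

    def test_runs_are_consecutive_spells(self):
        vals = [0, 2000, 2000, 0, 3000, 0, 2500, 2500, 2500]
        out = classify_days(self.make_series(vals), self.threshold(1518))
        assert out["runs"] == [2, 1, 3]

    def test_exceedance_count_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 5000, 60)
        counts = [
            classify_days(self.make_series(vals), self.threshold(x))["n_exceed"]
            for x in (500, 1518, 3000, 6000)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScreenRequest:
    def threshold(self):
        return invert_threshold(reference_regression(), DEFAULT_Y_TARGET)

    def test_capacity_available_authorizes(self):
        table = FuelParameterTable.default()
        # choose an area projecting ~400 t on deciduous forest
        b, c, ef = table.params(4)
        area = 400.0 / (b * c * ef)
        out = screen_request(
            {"area_km2": area, "lc_class": 4, "date": "2024-02-01"},
            {"committed_tons_today": 1000.0, "threshold": self.threshold(),
             "forecast_flag": "favorable"},
            table,
        )
        assert out["decision"] == "authorize"
        assert out["projected_tons"] == pytest.approx(400.0)

    def test_over_budget_restricts(self):
        table = FuelParameterTable.default()
        b, c, ef = table.params(4)
        area = 200.0 / (b * c * ef)
        out = screen_request(
            {"area_km2": area, "lc_class": 4, "date": "2024-03-15"},
            {"committed_tons_today": 1400.0, "threshold": self.threshold()},
            table,
        )
        assert out["decision"] == "restrict"

    def test_adverse_forecast_overrides_budget(self):
        out = screen_request(
            {"area_km2": 0.1, "lc_class": 12, "date": "2024-03-15"},
            {"committed_tons_today": 0.0, "threshold": self.threshold(),
             "forecast_flag": "adverse"},
        )
        assert out["decision"] == "restrict"

    def test_non_burnable_class_authorizes_with_note(self):
        out = screen_request(
            {"area_km2": 5.0, "lc_class": 17, "date": "2024-03-15"},
            {"committed_tons_today": 5000.0, "threshold": self.threshold()},
        )
        assert out["decision"] == "authorize"
        assert out["projected_tons"] == 0.0
        assert "non-burnable" in out["note"]


class TestSpatialCorr:
    def test_proportional_cell_has_r_one(self):
        rng = np.random.default_rng(0)
        frp = rng.uniform(1, 10, size=(10, 3, 3))
        emis = 2.5 * frp
        r = spatial_corr(frp, emis)
        assert np.allclose(r, 1.0)

    def test_sparse_cells_masked(self):
        frp = np.zeros((10, 2, 2))
        emis = np.zeros((10, 2, 2))
        frp[0, 0, 0] = 1.0
        emis[0, 0, 0] = 2.0  # only one active day
        r = spatial_corr(frp, emis)
        assert np.isnan(r).all()

    def test_misaligned_grids_rejected(self):
        with pytest.raises(ArgumentError):
            spatial_corr(np.zeros((5, 2, 2)), np.zeros((5, 3, 3)))

    def test_noisy_coupling_matches_analytic_r(self):
        """Cells with emis = a·frp + noise: mean map r ≈ the closed-form
        correlation of a linear signal plus independent Gaussian noise."""
        rng = np.random.default_rng(7)
        t = 200
        frp = rng.uniform(1, 10, size=(t, 4, 4))
        sigma = 2.0
        emis = 3.0 * frp + rng.normal(0, sigma, size=(t, 4, 4))
        sig = 3.0 * np.std(frp)  # signal sd; frp ~ U(1,10)
        expected = sig / np.hypot(sig, sigma)
        r = spatial_corr(frp, emis)
        assert abs(np.nanmean(r) - expected) < 0.05
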