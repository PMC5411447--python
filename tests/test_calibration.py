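"""Per-site parameter calibration and the climate exponent modifier."""

import dataclasses
import math

import numpy as np
import pytest

from allocane import (
    CalibrationResult,
    ClimateVariable,
    Crop,
    FixedParameter,
    PowerModel,
    Predictor,
    Provenance,
    SyntheticConfig,
    adjusted_predict,
    calibrate_coefficient,
    calibrate_exponent,
    fit_climate_modifier,
    noise_free,
    predict,
    simulate_validation_set,
    true_exponent,
)
from allocane.calibration import _golden_section, adjusted_model

from conftest import make_site


def napier_model(a=151.26, b=0.68):
    return PowerModel(Crop.NAPIERGRASS, Predictor.D, a, b,
                      Provenance.SITE_SPECIFIC, "site_specific_D")


def _site_obs(rainfall, seed=3, b_offset=0.0, noise=0.0):
    cfg = SyntheticConfig.for_crop(
        Crop.NAPIERGRASS, seed=seed, noise_scale=noise, height_noise_cv=0.0,
        true_b0=0.68 + b_offset,
    )
    return simulate_validation_set(cfg, [make_site("S", rainfall=rainfall)])


class TestCalibrateExponent:
    def test_recovers_generating_exponent_noise_free(self):
        # data follow b_true = 0.78; model starts 0.1 low
        obs = _site_obs(rainfall=521.1)  # b = 0.68 + 2e-4·500 = 0.78
        res = calibrate_exponent(napier_model(b=0.68), obs)
        assert res.calibrated_value == pytest.approx(0.78, abs=1e-3)
        assert res.achieved_slope == pytest.approx(1.0, abs=1e-3)
        assert abs(res.achieved_intercept) / np.mean(
            [s.dry_mass for s in obs]
        ) <= 1e-3

    def test_already_calibrated_model_is_fixed_point(self):
        obs = _site_obs(rainfall=21.1)  # b = b0 = 0.68 exactly
        res = calibrate_exponent(napier_model(b=0.68), obs)
        assert res.calibrated_value == pytest.approx(0.68, abs=1e-4)
        assert res.objective_value < 1e-8

    def test_calibrated_exponent_monotone_in_generating_exponent(self):
        model = napier_model(b=0.68)
        rains = [21.1, 221.1, 421.1, 621.1]  # strictly increasing true b
        values = [
            calibrate_exponent(model, _site_obs(r)).calibrated_value
            for r in rains
        ]
        assert values == sorted(values)

    def test_boundary_optimum_warns(self):
        obs = _site_obs(rainfall=521.1)  # true b = 0.78
        with pytest.warns(RuntimeWarning, match="boundary"):
            calibrate_exponent(napier_model(b=0.45), obs, bounds=(0.4, 0.5))

    def test_preconditions(self):
        obs = _site_obs(rainfall=100.0)
        with pytest.raises(ValueError, match="bounds"):
            calibrate_exponent(napier_model(b=0.68), obs, bounds=(0.9, 2.0))
        with pytest.raises(ValueError):
            calibrate_exponent(napier_model(), obs[:4])


class TestCalibrateCoefficient:
    def test_halved_predictions_double_the_coefficient(self):
        obs = _site_obs(rainfall=21.1)  # y = 151.26·D^0.68 exactly
        res = calibrate_coefficient(napier_model(a=151.26 / 2, b=0.68), obs)
        assert res.fixed_parameter is FixedParameter.B_FIXED
        assert res.calibrated_value == pytest.approx(151.26, rel=1e-10)
        assert res.achieved_slope == pytest.approx(1.0, rel=1e-10)

    def test_true_model_is_identity(self):
        obs = _site_obs(rainfall=21.1)
        res = calibrate_coefficient(napier_model(), obs)
        assert res.calibrated_value == pytest.approx(151.26, rel=1e-10)

    def test_closed_form_matches_golden_section(self, rng):
        for seed in range(5):
            obs = _site_obs(rainfall=300.0, seed=seed, noise=0.08)
            model = napier_model()
            res = calibrate_coefficient(model, obs, check=False)
            x = np.array([s.stalk_diameter for s in obs])
            y = np.array([s.dry_mass for s in obs])
            g = x**model.exponent_b
            obar = y.mean()

            def J(a):
                n = len(y)
                p = a * g
                slope = np.cov(y, p, bias=True)[0, 1] / np.var(y)
                intercept = p.mean() - slope * y.mean()
                return (slope - 1) ** 2 + (intercept / obar) ** 2

            a_search = _golden_section(J, res.calibrated_value / 5,
                                       res.calibrated_value * 5, tol=1e-10)
            # J is exactly quadratic in a, so one parabolic step through the
            # golden bracket removes the sqrt(eps) localization noise
            h = 1e-3 * a_search
            f0, f1, f2 = J(a_search - h), J(a_search), J(a_search + h)
            a_search += h * (f0 - f2) / (2 * (f0 - 2 * f1 + f2))
            assert res.calibrated_value == pytest.approx(a_search, rel=1e-8)


def _calibration_results(b_values, sites):
    return [
        CalibrationResult(site_id=s.site_id, crop_id=Crop.NAPIERGRASS,
                          fixed_parameter=FixedParameter.A_FIXED,
                          calibrated_value=b, achieved_slope=1.0,
                          achieved_intercept=0.0, objective_value=0.0)
        for b, s in zip(b_values, sites)
    ]


FOUR_SITES = [
    make_site("F718", rainfall=169.9, solar=22.8, temp=24.5, rh=74, wind=15.7),
    make_site("F609", rainfall=485.4, solar=19.8, temp=22.2, rh=75, wind=14.5),
    make_site("F410", rainfall=305.1, solar=22.5, temp=23.4, rh=75, wind=9.7),
    make_site("Kula", rainfall=426.0, solar=16.0, temp=19.1, rh=80, wind=4.4),
]


class TestClimateModifier:
    def test_exact_linear_truth_recovered(self):
        b = [0.6 + 2e-4 * s.rainfall for s in FOUR_SITES]
        mod = fit_climate_modifier(_calibration_results(b, FOUR_SITES), FOUR_SITES)
        assert mod.selected_variable is ClimateVariable.RAINFALL
        assert mod.r_squared_by_variable[ClimateVariable.RAINFALL] == pytest.approx(1.0)
        assert mod.intercept_c0 == pytest.approx(0.6, rel=1e-8)
        assert mod.slope_c1 == pytest.approx(2e-4, rel=1e-8)

    def test_noisy_linear_truth_still_selects_rainfall(self):
        rng = np.random.default_rng(11)
        b = [0.6 + 2e-4 * s.rainfall + 0.003 * rng.standard_normal()
             for s in FOUR_SITES]
        mod = fit_climate_modifier(_calibration_results(b, FOUR_SITES), FOUR_SITES)
        assert mod.selected_variable is ClimateVariable.RAINFALL
        assert mod.r_squared_by_variable[ClimateVariable.RAINFALL] > 0.95

    def test_constant_values_warn_no_covariate(self):
        with pytest.warns(RuntimeWarning, match="no covariate"):
            mod = fit_climate_modifier(
                _calibration_results([0.7] * 4, FOUR_SITES), FOUR_SITES
            )
        assert all(r2 == pytest.approx(0.0, abs=1e-12)
                   for r2 in mod.r_squared_by_variable.values())

    def test_zero_variance_covariate_skipped(self):
        sites = [dataclasses.replace(s, wind_speed=10.0) for s in FOUR_SITES]
        b = [0.6 + 2e-4 * s.rainfall for s in sites]
        with pytest.warns(RuntimeWarning, match="wind_speed"):
            mod = fit_climate_modifier(_calibration_results(b, sites), sites)
        assert ClimateVariable.WIND_SPEED not in mod.r_squared_by_variable

    def test_too_few_sites_rejected(self):
        b = [0.6, 0.7]
        with pytest.raises(ValueError, match="3 sites"):
            fit_climate_modifier(_calibration_results(b, FOUR_SITES[:2]),
                                 FOUR_SITES[:2])

    def test_affine_covariate_rescaling_is_equivariant(self):
        b = [0.6 + 2e-4 * s.rainfall for s in FOUR_SITES]
        mod = fit_climate_modifier(_calibration_results(b, FOUR_SITES), FOUR_SITES)
        scaled = [dataclasses.replace(s, rainfall=0.1 * s.rainfall + 50)
                  for s in FOUR_SITES]
        mod2 = fit_climate_modifier(_calibration_results(b, scaled), scaled)
        assert mod2.selected_variable is mod.selected_variable
        for orig, new in zip(FOUR_SITES, scaled):
            assert mod2.exponent_at(new.rainfall) == pytest.approx(
                mod.exponent_at(orig.rainfall), rel=1e-10
            )


class TestAdjustedPredict:
    def _null_modifier(self, b):
        from allocane import ClimateModifier
        return ClimateModifier(Crop.NAPIERGRASS, ClimateVariable.RAINFALL,
                               slope_c1=0.0, intercept_c0=b,
                               r_squared_by_variable={})

    def test_null_modifier_matches_predict(self):
        m = napier_model()
        mod = self._null_modifier(m.exponent_b)
        for d in (0.7, 1.0, 2.5):
            assert adjusted_predict(m, mod, 500.0, D=d) == predict(m, D=d)

    def test_unit_diameter_returns_coefficient_regardless_of_modifier(self):
        m = napier_model()
        mod = self._null_modifier(1.23)
        assert adjusted_predict(m, mod, 900.0, D=1.0) == m.coefficient_a

    def test_out_of_range_exponent_warns_but_returns(self):
        m = napier_model()
        mod = self._null_modifier(3.5)
        with pytest.warns(RuntimeWarning, match="sanity"):
            val = adjusted_predict(m, mod, 100.0, D=2.0)
        assert math.isfinite(val)

    def test_provenance_marked_adjusted(self):
        m = napier_model()
        adj = adjusted_model(m, self._null_modifier(0.7), 300.0)
        assert adj.provenance is Provenance.RAINFALL_ADJUSTED
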