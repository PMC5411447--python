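"""Site calibration of power-model parameters and climate adjustment.

A site's systematic error is removed by re-solving one parameter of the
power model so that OLS of predicted on observed attains slope 1 and
intercept 0. "Near 1 slope, near 0 intercept" is formalized as the
objective

    J = (slope − 1)² + (intercept / Ō)²

with the intercept scaled by the mean observed mass so the two terms are
comparable. Calibrated exponents from several sites are then regressed on
each climate covariate; the best single covariate (rainfall, in practice)
yields a linear exponent modifier b(x) = c0 + c1·x and a climate-adjusted
predictor.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
from scipy import stats

from .types import (
    CalibrationResult,
    ClimateModifier,
    ClimateVariable,
    Crop,
    FixedParameter,
    PowerModel,
    Provenance,
    SiteWeather,
    StalkObservation,
)
from .fitting import predict, predictor_values
from .validation import one_to_one_regression

log = logging.getLogger(__name__)

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0


def _golden_section(f, lo: float, hi: float, tol: float = 1e-6) -> float:
    """Minimize a unimodal scalar function on [lo, hi] by golden section."""
    a, b = lo, hi
    c = b - _INVPHI * (b - a)
    d = a + _INVPHI * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - _INVPHI * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _INVPHI * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _objective(slope: float, intercept: float, obar: float) -> float:
    return (slope - 1.0) ** 2 + (intercept / obar) ** 2


def _site_label(obs: list[StalkObservation]) -> str:
    sites = {s.site_id for s in obs}
    return obs[0].site_id if len(sites) == 1 else "pooled"


def _xy(model: PowerModel, obs: list[StalkObservation]) -> tuple[np.ndarray, np.ndarray]:
    D = np.array([s.stalk_diameter for s in obs])
    H = np.array([s.dewlap_height for s in obs])
    y = np.array([s.dry_mass for s in obs])
    x = predictor_values(model.predictor, D, H)
    return x, y


def calibrate_exponent(
    model: PowerModel,
    obs: list[StalkObservation],
    bounds: tuple[float, float] = (0.1, 2.0),
    grid_points: int = 64,
    tol: float = 1e-6,
) -> CalibrationResult:
    """Hold a fixed, re-solve the exponent b for a 1:1 predicted-observed fit.

    A coarse grid scan over ``bounds`` brackets the optimum (J can be mildly
    non-convex in b); golden-section search then refines it to ``tol``.
    Warns if the optimum sits at a boundary.
    """
    b_lo, b_hi = bounds
    if not b_lo < model.exponent_b < b_hi:
        raise ValueError("bounds must contain the model exponent")
    if len(obs) < 5:
        raise ValueError("need at least 5 observations")
    x, y = _xy(model, obs)
    if np.any(x <= 0):
        raise ValueError("all predictor values must be > 0")
    if np.ptp(y) == 0:
        raise ValueError("degenerate observations: constant dry mass")
    obar = float(y.mean())
    a = model.coefficient_a

    def J(b: float) -> float:
        slope, intercept, _ = one_to_one_regression(a * x**b, y)
        return _objective(slope, intercept, obar)

    grid = np.linspace(b_lo, b_hi, grid_points)
    jvals = [J(b) for b in grid]
    i = int(np.argmin(jvals))
    if i in (0, grid_points - 1):
        warnings.warn("calibration optimum at boundary of the exponent bounds", RuntimeWarning)
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    b_star = _golden_section(J, lo, hi, tol=tol)
    slope, intercept, _ = one_to_one_regression(a * x**b_star, y)
    return CalibrationResult(
        site_id=_site_label(obs),
        crop_id=model.crop_id,
        fixed_parameter=FixedParameter.A_FIXED,
        calibrated_value=float(b_star),
        achieved_slope=slope,
        achieved_intercept=intercept,
        objective_value=_objective(slope, intercept, obar),
    )


def calibrate_coefficient(
    model: PowerModel,
    obs: list[StalkObservation],
    bounds: tuple[float, float] | None = None,
    check: bool = True,
) -> CalibrationResult:
    """Hold b fixed, re-solve the coefficient a.

    Both the 1:1 slope and intercept are linear in a, so J(a) is quadratic
    with the closed-form minimizer a* = m / (m² + q²), where m and q are the
    slope and scaled intercept of the unit-coefficient predictions. The
    closed form is cross-checked against a golden-section search.
    """
    if len(obs) < 5:
        raise ValueError("need at least 5 observations")
    x, y = _xy(model, obs)
    if np.ptp(y) == 0:
        raise ValueError("degenerate observations: constant dry mass")
    obar = float(y.mean())
    g = x**model.exponent_b  # predictions at a = 1
    m, c, _ = one_to_one_regression(g, y)  # slope(a) = a·m, intercept(a) = a·c
    q = c / obar
    a_star = m / (m**2 + q**2)
    if bounds is not None:
        a_star = float(np.clip(a_star, *bounds))

    def J(a: float) -> float:
        return _objective(a * m, a * c, obar)

    if check:
        lo, hi = bounds if bounds is not None else (a_star / 10, a_star * 10)
        a_search = _golden_section(J, lo, hi, tol=1e-10 * max(abs(a_star), 1.0))
        if abs(a_search - a_star) > 1e-6 * max(abs(a_star), 1.0):
            warnings.warn(
                f"closed-form coefficient {a_star:.6g} differs from search {a_search:.6g}",
                RuntimeWarning,
            )
    return CalibrationResult(
        site_id=_site_label(obs),
        crop_id=model.crop_id,
        fixed_parameter=FixedParameter.B_FIXED,
        calibrated_value=float(a_star),
        achieved_slope=a_star * m,
        achieved_intercept=a_star * c,
        objective_value=J(a_star),
    )


def fit_climate_modifier(
    results: list[CalibrationResult],
    weather: list[SiteWeather],
) -> ClimateModifier:
    """Regress per-site calibrated values on each climate covariate.

    One simple OLS per covariate (four sites cannot support a multivariate
    fit); the covariate with the highest R² is selected, ties resolved in
    favor of rainfall. Zero-variance covariates are skipped with a warning.
    """
    if len(results) < 3:
        raise ValueError("need calibrated values from at least 3 sites")
    crops = {r.crop_id for r in results}
    fixed = {r.fixed_parameter for r in results}
    if len(crops) > 1 or len(fixed) > 1:
        raise ValueError("results must share one crop and one fixed_parameter")
    wx = {w.site_id: w for w in weather if w.crop_id in crops}
    missing = [r.site_id for r in results if r.site_id not in wx]
    if missing:
        raise ValueError(f"no weather record for site(s) {missing}")

    values = np.array([r.calibrated_value for r in results])
    r2_by: dict[ClimateVariable, float] = {}
    coefs: dict[ClimateVariable, tuple[float, float]] = {}
    for var in ClimateVariable:
        cov = np.array([wx[r.site_id].covariate(var) for r in results])
        if np.ptp(cov) == 0:
            warnings.warn(f"covariate {var.value} has zero variance; skipped", RuntimeWarning)
            continue
        res = stats.linregress(cov, values)
        r2 = float(res.rvalue**2)
        # constant calibrated values give an undefined correlation: no signal
        r2_by[var] = r2 if math.isfinite(r2) else 0.0
        coefs[var] = (float(res.intercept), float(res.slope))
    if not r2_by:
        raise ValueError("no covariate with variance across sites")

    best_r2 = max(r2_by.values())
    if best_r2 < 1e-12:
        warnings.warn("no covariate explains the calibrated values", RuntimeWarning)
    if (
        ClimateVariable.RAINFALL in r2_by
        and r2_by[ClimateVariable.RAINFALL] >= best_r2 - 1e-12
    ):
        selected = ClimateVariable.RAINFALL
    else:
        selected = max(r2_by, key=lambda v: r2_by[v])
    c0, c1 = coefs[selected]
    return ClimateModifier(
        crop_id=results[0].crop_id,
        selected_variable=selected,
        slope_c1=c1,
        intercept_c0=c0,
        r_squared_by_variable=r2_by,
    )


def adjusted_model(
    model: PowerModel, modifier: ClimateModifier, covariate_value: float
) -> PowerModel:
    """Site-adjusted copy of ``model`` with exponent b(x) = c0 + c1·x."""
    b = modifier.exponent_at(covariate_value)
    if not 0 <= b <= 3:
        warnings.warn(f"adjusted exponent {b:.3g} outside sanity range [0, 3]", RuntimeWarning)
    return PowerModel(
        crop_id=model.crop_id,
        predictor=model.predictor,
        coefficient_a=model.coefficient_a,
        exponent_b=b,
        provenance=Provenance.RAINFALL_ADJUSTED,
        source_label=f"{model.source_label}_adjusted_{modifier.selected_variable.value}",
    )


def adjusted_predict(
    model: PowerModel,
    modifier: ClimateModifier,
    covariate_value: float,
    D=None,
    H=None,
):
    """Predict AGB (g) with the climate-adjusted exponent."""
    if not math.isfinite(covariate_value):
        raise ValueError("covariate_value must be finite")
    return predict(adjusted_model(model, modifier, covariate_value), D=D, H=H)
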