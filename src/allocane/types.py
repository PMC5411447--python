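"""Typed records shared by every stage of the allometry pipeline.

All records are frozen dataclasses that validate their own invariants at
construction, so a record that exists is a record that is internally
consistent. Units follow the package convention: stalk diameter (D) and
dewlap height (H) in cm, dry mass in g per stalk, rainfall in mm.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class Crop(str, enum.Enum):
    """The three perennial C4 grasses the models cover."""

    NAPIERGRASS = "napiergrass"
    ENERGYCANE = "energycane"
    SUGARCANE = "sugarcane"


class Predictor(str, enum.Enum):
    """Functional form of a power model's predictor term.

    ``D`` and ``H`` are plain power laws Y = a·X^b; ``D_times_H`` uses the
    product of both measurements; ``logD_exp_form`` is the published
    exp[c + b·ln D] form, algebraically a power law with a = exp(c).
    """

    D = "D"
    H = "H"
    D_TIMES_H = "D_times_H"
    LOG_D_EXP = "logD_exp_form"


class Provenance(str, enum.Enum):
    SITE_SPECIFIC = "site_specific"
    GENERALIZED = "generalized"
    RAINFALL_ADJUSTED = "rainfall_adjusted"


class FixedParameter(str, enum.Enum):
    """Which power-law parameter was held constant during calibration."""

    A_FIXED = "a_fixed"
    B_FIXED = "b_fixed"


class ClimateVariable(str, enum.Enum):
    """Covariates recorded in the site weather summaries."""

    SOLAR_RADIATION = "solar_radiation"
    AIR_TEMPERATURE = "air_temperature"
    RAINFALL = "rainfall"
    RELATIVE_HUMIDITY = "relative_humidity"
    WIND_SPEED = "wind_speed"


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class StalkObservation:
    """One destructively harvested stalk.

    ``stalk_diameter`` is basal D (cm) measured 20 cm above the soil at the
    cut point; ``dewlap_height`` is H (cm) from the base cut to the most
    recently exposed leaf dewlap; ``dry_mass`` is oven-dry mass (g).
    """

    crop_id: Crop
    site_id: str
    replicate: int
    stalk_diameter: float
    dewlap_height: float
    dry_mass: float

    def __post_init__(self) -> None:
        _require(self.stalk_diameter > 0, "stalk_diameter must be > 0")
        _require(self.dewlap_height > 0, "dewlap_height must be > 0")
        _require(self.dry_mass > 0, "dry_mass must be > 0")
        _require(self.replicate >= 1, "replicate must be >= 1")


@dataclass(frozen=True)
class SiteWeather:
    """Weather summary for one (site, crop) observation period.

    solar_radiation MJ/m², air_temperature °C, rainfall mm,
    relative_humidity %, wind_speed km/hr.
    """

    site_id: str
    crop_id: Crop
    solar_radiation: float
    air_temperature: float
    rainfall: float
    relative_humidity: float
    wind_speed: float

    def __post_init__(self) -> None:
        _require(self.rainfall >= 0, "rainfall must be >= 0")
        _require(
            0 <= self.relative_humidity <= 100,
            "relative_humidity must be in [0, 100]",
        )
        for name in (
            "solar_radiation",
            "air_temperature",
            "rainfall",
            "relative_humidity",
            "wind_speed",
        ):
            _require(math.isfinite(getattr(self, name)), f"{name} must be finite")

    def covariate(self, variable: ClimateVariable) -> float:
        return float(getattr(self, variable.value))


@dataclass(frozen=True)
class PowerModel:
    """Allometric power model Y = a·X^b predicting dry mass (g).

    Evaluating the model at predictor value 1 returns ``coefficient_a``
    exactly (power identity), which anchors the units of ``a`` to g.
    """

    crop_id: Crop
    predictor: Predictor
    coefficient_a: float
    exponent_b: float
    provenance: Provenance
    source_label: str

    def __post_init__(self) -> None:
        _require(self.coefficient_a > 0, "coefficient_a must be > 0")
        _require(math.isfinite(self.exponent_b), "exponent_b must be finite")


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit battery for one fitted or evaluated model.

    ``rms`` is the residual mean square SSR/(n−k); ``aic``/``aicc`` use the
    least-squares form n·ln(SSR/n) + 2(k+1).
    """

    r_squared: float
    rms: float
    aic: float
    aicc: float
    p_value: float
    n: int
    k: int

    def __post_init__(self) -> None:
        _require(self.rms >= 0, "rms must be >= 0")
        _require(self.n > self.k, "need n > k")
        _require(self.r_squared <= 1 + 1e-12, "r_squared cannot exceed 1")
        _require(0 <= self.p_value <= 1, "p_value must be in [0, 1]")
        if self.n > self.k + 1:
            _require(self.aicc >= self.aic - 1e-12, "AICc must be >= AIC")


@dataclass(frozen=True)
class ValidationReport:
    """1:1 comparison of predicted vs observed AGB at independent sites.

    ``slope``/``intercept``/``r_squared`` come from OLS of predicted on
    observed; MSE is partitioned into its systematic part (displacement of
    that line from the 1:1 line) and unsystematic part (scatter about it),
    which sum to MSE exactly. ``d_index`` is Willmott's index of agreement;
    ``model_efficiency`` the Nash–Sutcliffe statistic.
    """

    slope: float
    intercept: float
    r_squared: float
    mse: float
    mse_systematic: float
    mse_unsystematic: float
    d_index: float
    model_efficiency: float
    n: int

    def __post_init__(self) -> None:
        _require(self.mse >= 0, "mse must be >= 0")
        _require(0 <= self.d_index <= 1 + 1e-12, "d_index must be in [0, 1]")
        _require(self.model_efficiency <= 1 + 1e-12, "model_efficiency <= 1")
        _require(0 <= self.r_squared <= 1 + 1e-12, "r_squared must be in [0, 1]")
        gap = abs(self.mse - (self.mse_systematic + self.mse_unsystematic))
        tol = 1e-9 * max(self.mse, 1e-300)
        _require(gap <= max(tol, 1e-12), "MSE components must sum to MSE")


@dataclass(frozen=True)
class CalibrationResult:
    """Per-site re-solution of one power-model parameter for a 1:1 fit."""

    site_id: str
    crop_id: Crop
    fixed_parameter: FixedParameter
    calibrated_value: float
    achieved_slope: float
    achieved_intercept: float
    objective_value: float

    def __post_init__(self) -> None:
        _require(self.objective_value >= 0, "objective_value must be >= 0")


@dataclass(frozen=True)
class ClimateModifier:
    """Linear relation of a calibrated power-law parameter to one climate
    covariate, b(x) = c0 + c1·x, selected as the covariate with the highest
    per-variable R²."""

    crop_id: Crop
    selected_variable: ClimateVariable
    slope_c1: float
    intercept_c0: float
    r_squared_by_variable: dict[ClimateVariable, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _require(math.isfinite(self.slope_c1), "slope_c1 must be finite")
        _require(math.isfinite(self.intercept_c0), "intercept_c0 must be finite")
        if self.r_squared_by_variable:
            best = max(self.r_squared_by_variable.values())
            _require(
                self.r_squared_by_variable.get(self.selected_variable, -math.inf)
                >= best - 1e-12,
                "selected_variable must attain the maximum R²",
            )

    def exponent_at(self, covariate_value: float) -> float:
        """b(x) = c0 + c1·x."""
        return self.intercept_c0 + self.slope_c1 * covariate_value
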