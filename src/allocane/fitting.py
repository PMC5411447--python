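"""Power-model fitting, model comparison, and carbon conversion.

The allometric target is untransformed nonlinear least squares on
Y = a·X^b (log transformation does not stabilize the error variance for
these data, so the additive-error fit is the one reported); log-log OLS is
kept as the initializer and exposed separately for comparison.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .types import Crop, FitDiagnostics, PowerModel, Predictor, Provenance

log = logging.getLogger(__name__)


class FitError(RuntimeError):
    """Nonlinear fit failed; carries the best iterate found."""

    def __init__(self, msg: str, best_params=None, grad_norm=None):
        super().__init__(msg)
        self.best_params = best_params
        self.grad_norm = grad_norm


def predictor_values(
    predictor: Predictor, D: np.ndarray | float | None, H: np.ndarray | float | None
) -> np.ndarray:
    """Assemble the model's X from the available measurements."""
    if predictor in (Predictor.D, Predictor.LOG_D_EXP):
        if D is None:
            raise ValueError(f"predictor {predictor.value} requires D")
        return np.asarray(D, dtype=float)
    if predictor is Predictor.H:
        if H is None:
            raise ValueError("predictor H requires H")
        return np.asarray(H, dtype=float)
    if predictor is Predictor.D_TIMES_H:
        if D is None or H is None:
            missing = "D" if D is None else "H"
            raise ValueError(f"predictor D_times_H requires {missing}")
        return np.asarray(D, dtype=float) * np.asarray(H, dtype=float)
    raise ValueError(f"unknown predictor {predictor}")


def predict(model: PowerModel, D=None, H=None):
    """Evaluate Y = a·X^b (g). Scalar in, scalar out; array in, array out."""
    x = predictor_values(model.predictor, D, H)
    y = model.coefficient_a * x**model.exponent_b
    return float(y) if np.ndim(y) == 0 else y


def fit_loglog(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """OLS of ln y on ln x; returns (a, b) on the natural scale.

    Used to start the nonlinear fit and available as the classical
    back-transformed alternative.
    """
    lx, ly = np.log(x), np.log(y)
    b, lna = np.polyfit(lx, ly, 1)
    return math.exp(lna), float(b)


def goodness_of_fit(y_obs, y_pred, n: int, k: int) -> FitDiagnostics:
    """Goodness-of-fit battery for a model with k parameters on n points.

    R² = 1 − SSR/SST_c; RMS = SSR/(n−k);
    AIC = n·ln(SSR/n) + 2(k+1) (least-squares form, error variance counted);
    AICc = AIC + 2(k+1)(k+2)/(n−k−2);
    p from F = [(SST_c − SSR)/(k−1)] / [SSR/(n−k)] on (k−1, n−k) df.
    A perfect fit (SSR = 0) reports AIC/AICc as −inf with a warning.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_obs) != len(y_pred):
        raise ValueError("y_obs and y_pred must have equal length")
    if n <= k + 1:
        raise ValueError("need n > k + 1")
    ssr = float(np.sum((y_obs - y_pred) ** 2))
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant response: corrected SST is zero")
    r2 = 1.0 - ssr / sst
    rms = ssr / (n - k)
    if ssr == 0:
        warnings.warn("perfect fit: AIC reported as -inf", RuntimeWarning)
        aic = aicc = -math.inf
        p = 0.0
    else:
        aic = n * math.log(ssr / n) + 2 * (k + 1)
        aicc = aic + 2 * (k + 1) * (k + 2) / (n - k - 2)
        f_stat = ((sst - ssr) / (k - 1)) / (ssr / (n - k))
        p = float(stats.f.sf(f_stat, k - 1, n - k))
    return FitDiagnostics(r_squared=r2, rms=rms, aic=aic, aicc=aicc, p_value=p, n=n, k=k)


def fit_power(
    x,
    y,
    predictor: Predictor,
    crop_id: Crop = Crop.NAPIERGRASS,
    source_label: str | None = None,
    max_iter: int = 500,
) -> tuple[PowerModel, FitDiagnostics]:
    """Fit Y = a·X^b by untransformed least squares.

    Started from the log-log OLS estimate and iterated until the relative
    change in SSR falls below 1e-10 (or ``max_iter`` evaluations, which
    raises :class:`FitError` carrying the best iterate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("all x and y must be > 0")
    if np.ptp(x) == 0:
        raise ValueError("degenerate predictor: all x equal")

    a0, b0 = fit_loglog(x, y)

    def resid(p):
        return p[0] * x ** p[1] - y

    res = optimize.least_squares(
        resid,
        x0=[a0, b0],
        method="trf",
        ftol=1e-10,
        xtol=1e-14,
        gtol=None,
        max_nfev=max_iter * 4,
    )
    grad_norm = float(np.linalg.norm(res.grad)) if res.grad is not None else math.nan
    if res.status == 0:
        raise FitError(
            f"power fit did not converge in {max_iter} iterations",
            best_params=tuple(res.x),
            grad_norm=grad_norm,
        )
    a, b = float(res.x[0]), float(res.x[1])
    if a <= 0:
        raise FitError("fit converged to non-positive coefficient", best_params=(a, b))
    model = PowerModel(
        crop_id=crop_id,
        predictor=predictor,
        coefficient_a=a,
        exponent_b=b,
        provenance=Provenance.SITE_SPECIFIC,
        source_label=source_label or f"site_specific_{predictor.value}",
    )
    diag = goodness_of_fit(y, a * x**b, n=n, k=2)
    return model, diag


# --- published generalized models -------------------------------------------

#: Fixed-coefficient generalized equations for tropical woody/shrub biomass,
#: expressed as power models. The ln-D form exp[-2.134 + 2.530·ln D] is
#: algebraically exp(-2.134)·D^2.530.
GENERALIZED_FORMS: dict[str, tuple[Predictor, float, float]] = {
    "generalized_lnD": (Predictor.LOG_D_EXP, math.exp(-2.134), 2.530),
    "generalized_H": (Predictor.H, 5.37e-5, 2.714),
    "generalized_DH": (Predictor.D_TIMES_H, 0.0612, 1.5811),
}


def generalized_models(crop: Crop) -> dict[str, PowerModel]:
    """The three published generalized equations, tagged with ``crop`` for
    bookkeeping (their coefficients do not depend on the crop)."""
    return {
        label: PowerModel(
            crop_id=crop,
            predictor=pred,
            coefficient_a=a,
            exponent_b=b,
            provenance=Provenance.GENERALIZED,
            source_label=label,
        )
        for label, (pred, a, b) in GENERALIZED_FORMS.items()
    }


# --- model ranking -----------------------------------------------------------


def rank_models(
    candidates: list[tuple[str, FitDiagnostics]],
    tie_threshold: float = 0.005,
) -> tuple[list[str], dict[str, str]]:
    """Order candidate models by goodness of fit on common observations.

    Primary sort is descending R²; candidates whose R² is within
    ``tie_threshold`` of a cluster's best are ordered by ascending AICc,
    then ascending RMS. Returns the ordered labels plus the per-criterion
    winners (highest R², lowest RMS/AIC/AICc/p).
    """
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidates to rank")
    ns = {d.n for _, d in candidates}
    if len(ns) > 1:
        raise ValueError(f"candidates scored on different n: {sorted(ns)}")

    by_r2 = sorted(enumerate(candidates), key=lambda t: (-t[1][1].r_squared, t[0]))
    ordered: list[str] = []
    i = 0
    while i < len(by_r2):
        lead_r2 = by_r2[i][1][1].r_squared
        cluster = [by_r2[i]]
        j = i + 1
        while j < len(by_r2) and lead_r2 - by_r2[j][1][1].r_squared < tie_threshold:
            cluster.append(by_r2[j])
            j += 1
        cluster.sort(key=lambda t: (t[1][1].aicc, t[1][1].rms, t[0]))
        ordered.extend(label for _, (label, _) in cluster)
        i = j

    winners = {
        "r_squared": max(candidates, key=lambda c: c[1].r_squared)[0],
        "rms": min(candidates, key=lambda c: c[1].rms)[0],
        "aic": min(candidates, key=lambda c: c[1].aic)[0],
        "aicc": min(candidates, key=lambda c: c[1].aicc)[0],
        "p_value": min(candidates, key=lambda c: c[1].p_value)[0],
    }
    return ordered, winners


# --- carbon conversion -------------------------------------------------------


@dataclass(frozen=True)
class CarbonFractionTable:
    """Crop-specific carbon concentration of dry biomass (fraction)."""

    fraction: dict[Crop, float] = field(
        default_factory=lambda: {
            Crop.NAPIERGRASS: 0.424,
            Crop.ENERGYCANE: 0.430,
            Crop.SUGARCANE: 0.456,
        }
    )

    def __post_init__(self) -> None:
        for crop, f in self.fraction.items():
            if not 0 < f < 1:
                raise ValueError(f"carbon fraction for {crop} must be in (0, 1)")


DEFAULT_CARBON_FRACTIONS = CarbonFractionTable()


def c_stock(
    agb, crop_id: Crop, table: CarbonFractionTable = DEFAULT_CARBON_FRACTIONS
):
    """Carbon stock (g C) = AGB (g) × crop carbon concentration."""
    if crop_id not in table.fraction:
        raise KeyError(f"no carbon fraction for crop {crop_id}")
    agb_arr = np.asarray(agb, dtype=float)
    if np.any(agb_arr < 0):
        raise ValueError("AGB must be >= 0")
    out = agb_arr * table.fraction[crop_id]
    return float(out) if np.ndim(out) == 0 else out
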