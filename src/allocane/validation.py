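"""Predicted-versus-observed agreement statistics.

The suite follows the crop-model evaluation tradition: OLS of predicted on
observed against the 1:1 line, mean square error split into its systematic
part (the OLS line's displacement from the 1:1 line, i.e. correctable bias)
and unsystematic part (scatter about the line), Willmott's index of
agreement d, and the Nash–Sutcliffe model efficiency. All MSE quantities
divide by n (population form), which is what makes the decomposition an
exact identity.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .types import ValidationReport


def one_to_one_regression(predicted, observed) -> tuple[float, float, float]:
    """OLS with predicted as response and observed as regressor.

    Returns (slope, intercept, r_squared) where r_squared is the squared
    Pearson correlation.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if len(p) != len(o):
        raise ValueError("predicted and observed must have equal length")
    if len(o) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(o) <= 1e-10 * np.max(np.abs(o)):
        # spread at or near the float-representability floor: the regression
        # is numerically meaningless
        raise ValueError("observed values have zero variance")
    if np.ptp(p) == 0:
        # constant predictions: flat line, no linear association
        return 0.0, float(p[0]), 0.0
    res = stats.linregress(o, p)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def validate(predicted, observed) -> ValidationReport:
    """Full 1:1 agreement report for predicted vs observed AGB.

    With P̂ᵢ the OLS fit of P on O:
    MSE = mean (Pᵢ−Oᵢ)², MSE_s = mean (P̂ᵢ−Oᵢ)², MSE_u = mean (Pᵢ−P̂ᵢ)²
    (MSE_s + MSE_u = MSE exactly);
    d = 1 − Σ(Pᵢ−Oᵢ)² / Σ(|Pᵢ−Ō|+|Oᵢ−Ō|)²;
    efficiency = 1 − Σ(Pᵢ−Oᵢ)²/Σ(Oᵢ−Ō)².
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    slope, intercept, r2 = one_to_one_regression(p, o)
    n = len(o)
    # centered form of intercept + slope·o: algebraically identical, but
    # avoids catastrophic cancellation when observations barely vary
    p_hat = p.mean() + slope * (o - o.mean())
    sq_err = np.sum((p - o) ** 2)
    mse = float(sq_err / n)
    mse_s = float(np.sum((p_hat - o) ** 2) / n)
    mse_u = float(np.sum((p - p_hat) ** 2) / n)

    obar = o.mean()
    d_denom = float(np.sum((np.abs(p - obar) + np.abs(o - obar)) ** 2))
    if d_denom == 0:
        warnings.warn("degenerate agreement denominator; d defined as 1", RuntimeWarning)
        d = 1.0
    else:
        # the triangle inequality bounds d in [0, 1]; clamp float rounding
        d = float(np.clip(1.0 - sq_err / d_denom, 0.0, 1.0))
    efficiency = float(1.0 - sq_err / np.sum((o - obar) ** 2))

    return ValidationReport(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mse=mse,
        mse_systematic=mse_s,
        mse_unsystematic=mse_u,
        d_index=min(d, 1.0),
        model_efficiency=efficiency,
        n=n,
    )
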