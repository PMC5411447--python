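"""End-to-end study orchestration.

Runs the full workflow for each crop — simulate a development harvest, fit
site-specific D and H models and score the published generalized models,
rank them, convert to carbon stock, validate the best model at four
independent sites, calibrate the exponent per site, fit the rainfall
modifier, and re-validate the adjusted model — writing every artifact as
CSV plus a checksummed manifest. Reruns with an identical config produce
byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as aio
from .calibration import (
    adjusted_model,
    calibrate_exponent,
    fit_climate_modifier,
)
from .fitting import (
    DEFAULT_CARBON_FRACTIONS,
    c_stock,
    fit_power,
    generalized_models,
    goodness_of_fit,
    predict,
    rank_models,
)
from .synthetic import SyntheticConfig, simulate_development_set, simulate_validation_set
from .types import Crop, Predictor
from .validation import validate

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for one reproducible study run."""

    outdir: Path
    crops: list[Crop] = field(default_factory=lambda: list(Crop))
    seed: int = 42
    stalks_per_rep_dev: int = 10
    reps_dev: int = 3
    stalks_per_rep_val: int = 25
    reps_val: int = 3
    include_generalized: bool = True
    do_validation: bool = True
    do_calibration: bool = True
    do_adjustment: bool = True
    calibration_bounds: tuple[float, float] = (0.1, 2.0)
    synthetic_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        self.crops = [Crop(c) for c in self.crops]


def crop_seed(seed: int, crop: Crop) -> int:
    """Stable per-crop seed below 2^31."""
    return (seed * 1000003 + zlib.crc32(crop.value.encode())) % (2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_rows(path: Path, header: list[str], rows: list[list]) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([repr(v) if isinstance(v, float) else v for v in row])


def run_study(config: RunConfig) -> pd.DataFrame:
    """Execute all enabled stages for every crop; returns the manifest.

    Each manifest row records (crop, stage, artifact, path, sha256, status).
    A stage failure propagates after the manifest written so far is saved;
    disabled stages appear with status ``skipped``.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def add(crop: Crop, stage: str, name: str, path: Path | None, status="written"):
        manifest.append(
            {
                "crop": crop.value,
                "stage": stage,
                "artifact": name,
                "path": str(path.name) if path else "",
                "sha256": _sha256(path) if path else "",
                "status": status,
            }
        )

    dev_weather = {w.crop_id: w for w in aio.load_weather_fixture("development")}
    val_weather = aio.load_weather_fixture("validation")

    try:
        for crop in config.crops:
            _run_crop(config, crop, dev_weather[crop],
                      [w for w in val_weather if w.crop_id == crop], outdir, add)
    finally:
        mpath = outdir / "manifest.csv"
        df = pd.DataFrame(
            manifest,
            columns=["crop", "stage", "artifact", "path", "sha256", "status"],
        )
        df.to_csv(mpath, index=False)
    log.info("study complete: %d artifacts under %s", len(df), outdir)
    return df


def _run_crop(config: RunConfig, crop: Crop, dev_w, val_ws, outdir: Path, add) -> None:
    tag = crop.value
    syn = SyntheticConfig.for_crop(
        crop,
        seed=crop_seed(config.seed, crop),
        stalks_per_rep=config.stalks_per_rep_dev,
        reps_per_site=config.reps_dev,
        **config.synthetic_overrides,
    )
    log.info("%s: generator seed=%d a=%g b0=%g ref_rain=%g noise=%s/%g",
             tag, syn.seed, syn.true_a, syn.true_b0, syn.reference_rainfall,
             syn.noise_model, syn.noise_scale)

    # --- development harvest and model fitting
    dev = simulate_development_set(syn, dev_w)
    p_dev = outdir / f"{tag}_development_stalks.csv"
    aio.write_stalk_table(dev, p_dev)
    add(crop, "simulate", "development_stalks", p_dev)

    D = np.array([s.stalk_diameter for s in dev])
    H = np.array([s.dewlap_height for s in dev])
    y = np.array([s.dry_mass for s in dev])

    models = {}
    diags = {}
    m_d, g_d = fit_power(D, y, Predictor.D, crop_id=crop)
    m_h, g_h = fit_power(H, y, Predictor.H, crop_id=crop)
    models[m_d.source_label], diags[m_d.source_label] = m_d, g_d
    models[m_h.source_label], diags[m_h.source_label] = m_h, g_h
    if config.include_generalized:
        for label, gm in generalized_models(crop).items():
            pred = predict(gm, D=D, H=H)
            models[label] = gm
            diags[label] = goodness_of_fit(y, pred, n=len(y), k=2)

    ordered, winners = rank_models([(lbl, diags[lbl]) for lbl in models])
    p_fit = outdir / f"{tag}_fit_report.csv"
    _write_rows(
        p_fit,
        ["rank", "label", "predictor", "a", "b", "r_squared", "rms", "aic", "aicc", "p_value", "n", "k"],
        [
            [
                rank + 1,
                lbl,
                models[lbl].predictor.value,
                models[lbl].coefficient_a,
                models[lbl].exponent_b,
                diags[lbl].r_squared,
                diags[lbl].rms,
                diags[lbl].aic,
                diags[lbl].aicc,
                diags[lbl].p_value,
                diags[lbl].n,
                diags[lbl].k,
            ]
            for rank, lbl in enumerate(ordered)
        ],
    )
    add(crop, "fit", "fit_report", p_fit)
    log.info("%s: best model %s (criterion winners: %s)", tag, ordered[0], winners)
    best = models[ordered[0]]

    # --- carbon stock from the best model
    agb_pred = predict(best, D=D, H=H)
    cmass = c_stock(agb_pred, crop)
    p_c = outdir / f"{tag}_c_stock.csv"
    _write_rows(
        p_c,
        ["n", "carbon_fraction", "mean_pred_agb_g", "mean_c_stock_g"],
        [[len(dev), DEFAULT_CARBON_FRACTIONS.fraction[crop],
          float(np.mean(agb_pred)), float(np.mean(cmass))]],
    )
    add(crop, "c_stock", "c_stock_summary", p_c)

    if not config.do_validation:
        add(crop, "validation", "", None, status="skipped")
        add(crop, "calibration", "", None, status="skipped")
        add(crop, "adjustment", "", None, status="skipped")
        return

    # --- independent-site validation
    val = simulate_validation_set(
        syn, val_ws, stalks_per_rep=config.stalks_per_rep_val, reps_per_site=config.reps_val
    )
    p_val_stalks = outdir / f"{tag}_validation_stalks.csv"
    aio.write_stalk_table(val, p_val_stalks)
    add(crop, "simulate", "validation_stalks", p_val_stalks)

    vD = np.array([s.stalk_diameter for s in val])
    vH = np.array([s.dewlap_height for s in val])
    vy = np.array([s.dry_mass for s in val])
    report = validate(predict(best, D=vD, H=vH), vy)
    p_rep = outdir / f"{tag}_validation_report.csv"
    aio.write_report(report, p_rep)
    add(crop, "validation", "validation_report", p_rep)

    if not config.do_calibration:
        add(crop, "calibration", "", None, status="skipped")
        add(crop, "adjustment", "", None, status="skipped")
        return

    # --- per-site exponent calibration and climate modifier
    results = []
    rows = []
    for w in val_ws:
        site_obs = [s for s in val if s.site_id == w.site_id]
        res = calibrate_exponent(best, site_obs, bounds=config.calibration_bounds)
        results.append(res)
        rows.append([w.site_id, w.rainfall, res.calibrated_value,
                     res.achieved_slope, res.achieved_intercept, res.objective_value])
        log.info("%s/%s: calibrated b=%.6f (slope %.4f, intercept %.3f)",
                 tag, w.site_id, res.calibrated_value, res.achieved_slope,
                 res.achieved_intercept)
    p_cal = outdir / f"{tag}_calibration.csv"
    _write_rows(
        p_cal,
        ["site", "rain_mm", "calibrated_b", "achieved_slope", "achieved_intercept", "objective"],
        rows,
    )
    add(crop, "calibration", "calibration", p_cal)

    modifier = fit_climate_modifier(results, val_ws)
    p_mod = outdir / f"{tag}_modifier.csv"
    aio.write_report(modifier, p_mod)
    add(crop, "calibration", "climate_modifier", p_mod)
    log.info("%s: selected covariate %s (R²=%.4f)", tag,
             modifier.selected_variable.value,
             modifier.r_squared_by_variable[modifier.selected_variable])

    if not config.do_adjustment:
        add(crop, "adjustment", "", None, status="skipped")
        return

    # --- re-validate with the climate-adjusted exponent
    preds = np.empty(len(val))
    for w in val_ws:
        mask = np.array([s.site_id == w.site_id for s in val])
        adj = adjusted_model(best, modifier, w.covariate(modifier.selected_variable))
        preds[mask] = predict(adj, D=vD[mask], H=vH[mask])
    adj_report = validate(preds, vy)
    p_adj = outdir / f"{tag}_adjusted_validation_report.csv"
    aio.write_report(adj_report, p_adj)
    add(crop, "adjustment", "adjusted_validation_report", p_adj)


def report_summary(manifest: pd.DataFrame, outdir: str | Path) -> pd.DataFrame:
    """Human-readable one-row-per-(crop, stage) summary of a finished run.

    Missing artifacts are marked absent rather than raised.
    """
    outdir = Path(outdir)
    rows = []
    if manifest.empty:
        return pd.DataFrame(columns=["crop", "stage", "summary"])
    for (crop, stage), grp in manifest.groupby(["crop", "stage"], sort=False):
        if (grp["status"] == "skipped").all():
            rows.append({"crop": crop, "stage": stage, "summary": "skipped"})
            continue
        try:
            rows.append({"crop": crop, "stage": stage,
                         "summary": _stage_summary(stage, grp, outdir)})
        except FileNotFoundError:
            rows.append({"crop": crop, "stage": stage, "summary": "absent"})
    return pd.DataFrame(rows, columns=["crop", "stage", "summary"])


def _stage_summary(stage: str, grp: pd.DataFrame, outdir: Path) -> str:
    paths = {r["artifact"]: outdir / r["path"] for _, r in grp.iterrows() if r["path"]}
    if stage == "simulate":
        n = sum(len(pd.read_csv(p)) for p in paths.values())
        return f"{n} stalks simulated"
    if stage == "fit":
        df = pd.read_csv(paths["fit_report"])
        top = df.iloc[0]
        return f"best {top['label']} (R²={top['r_squared']:.3f})"
    if stage == "c_stock":
        df = pd.read_csv(paths["c_stock_summary"])
        return f"mean C stock {df['mean_c_stock_g'][0]:.1f} g/stalk"
    if stage in ("validation", "adjustment"):
        key = "validation_report" if stage == "validation" else "adjusted_validation_report"
        rep = aio.read_report(paths[key])
        return (f"slope={rep.slope:.3f} MSE={rep.mse:.1f} "
                f"d={rep.d_index:.3f} EF={rep.model_efficiency:.3f}")
    if stage == "calibration":
        mod = aio.read_report(paths["climate_modifier"])
        r2 = mod.r_squared_by_variable[mod.selected_variable]
        return f"covariate {mod.selected_variable.value} (R²={r2:.3f})"
    return "; ".join(sorted(paths))
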