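"""Delimited-text readers and writers for every record type.

All tabular interchange is comma-separated UTF-8 with a mandatory header
row and "." as the decimal separator. Floats are serialized with ``repr``
so that a write/read round trip reproduces each value bit-for-bit.

Column conventions
------------------
stalks.csv:  crop,site,rep,diameter_cm,dewlap_height_cm,dry_mass_g
weather.csv: site,crop,solar_mj_m2,temp_c,rain_mm,rh_pct,wind_kmh
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, fields
from importlib import resources
from pathlib import Path

import pandas as pd

from .types import (
    CalibrationResult,
    ClimateVariable,
    ClimateModifier,
    Crop,
    FitDiagnostics,
    FixedParameter,
    PowerModel,
    Predictor,
    Provenance,
    SiteWeather,
    StalkObservation,
    ValidationReport,
)

log = logging.getLogger(__name__)

STALK_COLUMNS = {
    "crop": "crop",
    "site": "site",
    "rep": "rep",
    "diameter_cm": "diameter_cm",
    "dewlap_height_cm": "dewlap_height_cm",
    "dry_mass_g": "dry_mass_g",
}

WEATHER_COLUMNS = ["site", "crop", "solar_mj_m2", "temp_c", "rain_mm", "rh_pct", "wind_kmh"]


class TableError(ValueError):
    """A delimited-text table violates the expected schema or contents."""


def read_stalk_table(
    path: str | Path,
    schema: dict[str, str] | None = None,
    max_reject_frac: float = 0.10,
) -> list[StalkObservation]:
    """Read stalk observations from a CSV file.

    ``schema`` maps the canonical column names (keys of ``STALK_COLUMNS``)
    to the names actually present in the file. Rows violating the record
    invariants (non-positive measurements, bad replicate) are rejected with
    a per-row diagnostic; the run aborts if more than ``max_reject_frac``
    of rows are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(STALK_COLUMNS)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        log.warning("%s: header-only stalk table, returning no records", path)
        return []

    records: list[StalkObservation] = []
    rejects: list[str] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        try:
            rec = StalkObservation(
                crop_id=Crop(str(row[colmap["crop"]])),
                site_id=str(row[colmap["site"]]),
                replicate=int(row[colmap["rep"]]),
                stalk_diameter=float(row[colmap["diameter_cm"]]),
                dewlap_height=float(row[colmap["dewlap_height_cm"]]),
                dry_mass=float(row[colmap["dry_mass_g"]]),
            )
        except (ValueError, TypeError) as exc:
            rejects.append(f"row {rownum}: {exc}")
            continue
        records.append(rec)
    for msg in rejects:
        log.warning("%s: rejected %s", path, msg)
    if rejects and len(rejects) > max_reject_frac * len(df):
        raise TableError(
            f"{path}: {len(rejects)}/{len(df)} rows rejected "
            f"(> {max_reject_frac:.0%}); first: {rejects[0]}"
        )
    log.info("%s: read %d stalk records (%d rejected)", path, len(records), len(rejects))
    return records


def write_stalk_table(records: list[StalkObservation], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(STALK_COLUMNS.values()))
        for r in records:
            w.writerow(
                [
                    r.crop_id.value,
                    r.site_id,
                    r.replicate,
                    repr(r.stalk_diameter),
                    repr(r.dewlap_height),
                    repr(r.dry_mass),
                ]
            )


def read_weather_table(path: str | Path) -> list[SiteWeather]:
    """Read (site, crop) weather summaries; duplicate keys are an error."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"{path}: missing required column(s) {missing}")
    records: list[SiteWeather] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        key = (str(row["site"]), str(row["crop"]))
        if key in seen:
            raise TableError(f"{path}: duplicate (site, crop) key {key}")
        seen.add(key)
        records.append(
            SiteWeather(
                site_id=key[0],
                crop_id=Crop(key[1]),
                solar_radiation=float(row["solar_mj_m2"]),
                air_temperature=float(row["temp_c"]),
                rainfall=float(row["rain_mm"]),
                relative_humidity=float(row["rh_pct"]),
                wind_speed=float(row["wind_kmh"]),
            )
        )
    return records


def write_weather_table(records: list[SiteWeather], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(WEATHER_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.site_id,
                    r.crop_id.value,
                    repr(r.solar_radiation),
                    repr(r.air_temperature),
                    repr(r.rainfall),
                    repr(r.relative_humidity),
                    repr(r.wind_speed),
                ]
            )


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("allocane").joinpath("data", name)))


def load_weather_fixture(which: str) -> list[SiteWeather]:
    """Load a packaged weather summary.

    ``which`` is ``"development"`` (single-site summaries recorded while the
    models were built) or ``"validation"`` (four-site summaries from the
    independent test harvests).
    """
    names = {"development": "table2_weather.csv", "validation": "table3_weather.csv"}
    if which not in names:
        raise ValueError(f"unknown weather fixture {which!r}; use {sorted(names)}")
    return read_weather_table(_fixture_path(names[which]))


@dataclass(frozen=True)
class RegistryEntry:
    """A published model plus the goodness-of-fit indices printed with it.

    The printed indices are carried for reference and ranking demonstrations
    only; the conventions behind the published AIC values are not known, so
    they are never recomputed.
    """

    model: PowerModel
    r_squared: float
    rms: float
    aic: float
    aicc: float


def load_model_registry(path: str | Path | None = None) -> list[RegistryEntry]:
    """Load the registry of site-specific and generalized published models.

    The ``logD_exp_form`` rows store the published log-scale intercept in
    ``ln_coefficient_a``; the power-law coefficient is its exponential.
    """
    p = Path(path) if path is not None else _fixture_path("table4_models.csv")
    df = pd.read_csv(p)
    entries: list[RegistryEntry] = []
    for _, row in df.iterrows():
        if pd.notna(row.get("coefficient_a")):
            a = float(row["coefficient_a"])
        else:
            a = math.exp(float(row["ln_coefficient_a"]))
        model = PowerModel(
            crop_id=Crop(str(row["crop"])),
            predictor=Predictor(str(row["predictor"])),
            coefficient_a=a,
            exponent_b=float(row["exponent_b"]),
            provenance=Provenance(str(row["provenance"])),
            source_label=str(row["source_label"]),
        )
        entries.append(
            RegistryEntry(
                model=model,
                r_squared=float(row["r_squared"]),
                rms=float(row["rms"]),
                aic=float(row["aic"]),
                aicc=float(row["aicc"]),
            )
        )
    return entries


def registry_model(
    entries: list[RegistryEntry], crop: Crop, source_label: str
) -> PowerModel:
    for e in entries:
        if e.model.crop_id == crop and e.model.source_label == source_label:
            return e.model
    raise KeyError(f"no registry model {source_label!r} for {crop.value}")


# --- labeled single-record reports -----------------------------------------

_REPORT_TYPES = {
    "ValidationReport": ValidationReport,
    "FitDiagnostics": FitDiagnostics,
    "CalibrationResult": CalibrationResult,
    "PowerModel": PowerModel,
    "ClimateModifier": ClimateModifier,
}

_ENUM_FIELDS = {
    "crop_id": Crop,
    "predictor": Predictor,
    "provenance": Provenance,
    "fixed_parameter": FixedParameter,
    "selected_variable": ClimateVariable,
}


def write_report(report, path: str | Path) -> None:
    """Write one record as labeled ``statistic,value`` rows.

    Every numeric field must be finite; floats are serialized with full
    precision so that :func:`read_report` reproduces the record exactly.
    """
    kind = type(report).__name__
    if kind not in _REPORT_TYPES:
        raise TypeError(f"cannot serialize {kind}")
    rows: list[tuple[str, str]] = [("record_type", kind)]
    for f in fields(report):
        val = getattr(report, f.name)
        if isinstance(val, float):
            if not math.isfinite(val):
                raise ValueError(f"{kind}.{f.name} is not finite; refusing to write")
            rows.append((f.name, repr(val)))
        elif isinstance(val, dict):
            for k, v in val.items():
                if not math.isfinite(v):
                    raise ValueError(f"{kind}.{f.name}[{k}] is not finite")
                rows.append((f"{f.name}.{getattr(k, 'value', k)}", repr(float(v))))
        else:
            rows.append((f.name, getattr(val, "value", str(val))))
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["statistic", "value"])
        w.writerows(rows)


def read_report(path: str | Path):
    """Read back a record written by :func:`write_report`."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    data = dict(rows[1:])
    kind = data.pop("record_type")
    cls = _REPORT_TYPES[kind]
    kwargs = {}
    maps: dict[str, dict] = {}
    for f in fields(cls):
        if f.name in data:
            raw = data[f.name]
            if f.name in _ENUM_FIELDS:
                kwargs[f.name] = _ENUM_FIELDS[f.name](raw)
            elif f.name in ("n", "k", "replicate"):
                kwargs[f.name] = int(raw)
            elif f.name in ("site_id", "source_label"):
                kwargs[f.name] = raw
            else:
                kwargs[f.name] = float(raw)
    # dict-valued fields were flattened to "field.key" rows
    for key, raw in data.items():
        if "." in key:
            fname, sub = key.split(".", 1)
            maps.setdefault(fname, {})[ClimateVariable(sub)] = float(raw)
    kwargs.update(maps)
    return cls(**kwargs)
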