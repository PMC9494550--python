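"""CSV dialects, YAML configuration, and the monitor registry.

All tabular interchange uses headed CSV with ``#`` comment lines.  Floats
are serialized with 17 significant digits so write/read round trips are
value-identical.  Parse errors name the offending line.

Dialects:

* spectrum:      ``e_low_MeV,e_high_MeV,fluence_per_cm2_per_Gy``
* layers:        ``energy_MeV,weight``
* response:      ``energy_MeV,response``
* conversion:    ``energy_MeV,h10_pSv_cm2``
* lineal energy: ``y_low_keV_um,y_high_keV_um,dose_Gy``
* charges:       ``charge_C``
* campaign:      ``irradiation_id,field_size_cm2,range_cm,modulation_cm,``
                 ``range_shifter,air_gap_cm,position,h10_uSv_per_Gy,rel_uncertainty``
"""

from __future__ import annotations

import csv
import io
import math
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scaling import (
    CAMPAIGN_COLUMNS,
    CampaignTable,
    Position,
    PositionCoefficients,
    ScalingModel,
    TreatmentPlan,
)
from .spectra import EnergyGrid, NeutronSpectrum, ProtonSource
from .response import ConversionTable, ResponseFunction
from .tepc import ChargeSeries, LinealEnergySpectrum

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_layers_csv",
    "read_response_csv",
    "read_conversion_csv",
    "read_lineal_csv",
    "write_lineal_csv",
    "read_charges_csv",
    "read_campaign_csv",
    "write_campaign_csv",
    "load_monitor_registry",
    "load_monitor",
    "save_model_yaml",
    "load_model_yaml",
    "ParseError",
]

_TRUE = {"1", "true", "yes"}
_FALSE = {"0", "false", "no"}


class ParseError(ValueError):
    """Malformed input file; message names the file and line."""


def _fmt(x: float) -> str:
    return f"{x:.17g}"


def _rows(path: Path, expected_header: list[str]):
    """Yield (line_number, fields) for data rows; validate the header."""
    with open(path, newline="") as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = next(csv.reader(io.StringIO(line)))
            fields = [f.strip() for f in fields]
            if not header_seen:
                if fields != expected_header:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {','.join(expected_header)!r}, "
                        f"got {','.join(fields)!r}"
                    )
                header_seen = True
                continue
            yield lineno, fields
        if not header_seen:
            raise ParseError(f"{path}: missing header {','.join(expected_header)!r}")


def _floats(path: Path, lineno: int, fields: list[str], n: int) -> list[float]:
    if len(fields) != n:
        raise ParseError(f"{path}:{lineno}: expected {n} columns, got {len(fields)}")
    try:
        return [float(f) for f in fields]
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from None


def read_spectrum_csv(path: str | Path, label: str | None = None) -> NeutronSpectrum:
    path = Path(path)
    lows, highs, flu = [], [], []
    for lineno, fields in _rows(path, ["e_low_MeV", "e_high_MeV", "fluence_per_cm2_per_Gy"]):
        lo, hi, f = _floats(path, lineno, fields, 3)
        if lo <= 0 or hi <= lo:
            raise ParseError(f"{path}:{lineno}: bin edges must satisfy 0 < e_low < e_high")
        if lows and not math.isclose(lo, highs[-1], rel_tol=1e-12):
            raise ParseError(f"{path}:{lineno}: bins must be contiguous and ascending")
        if f < 0:
            raise ParseError(f"{path}:{lineno}: negative fluence")
        lows.append(lo)
        highs.append(hi)
        flu.append(f)
    if not lows:
        raise ParseError(f"{path}: no data rows")
    grid = EnergyGrid(np.array(lows + [highs[-1]]))
    return NeutronSpectrum(grid, np.array(flu), label or path.stem)


def write_spectrum_csv(spectrum: NeutronSpectrum, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("e_low_MeV,e_high_MeV,fluence_per_cm2_per_Gy\n")
        for lo, hi, f in zip(
            spectrum.grid.lower, spectrum.grid.upper, spectrum.fluence
        ):
            fh.write(f"{_fmt(lo)},{_fmt(hi)},{_fmt(f)}\n")


def read_layers_csv(path: str | Path, two_sigma_fraction: float = 0.015) -> ProtonSource:
    path = Path(path)
    layers = []
    for lineno, fields in _rows(path, ["energy_MeV", "weight"]):
        e, w = _floats(path, lineno, fields, 2)
        layers.append((e, w))
    if not layers:
        raise ParseError(f"{path}: no data rows")
    return ProtonSource(tuple(layers), two_sigma_fraction=two_sigma_fraction)


def _read_two_column(path: Path, header: list[str]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    prev = -math.inf
    for lineno, fields in _rows(path, header):
        x, y = _floats(path, lineno, fields, 2)
        if x <= prev:
            raise ParseError(f"{path}:{lineno}: energies must be strictly increasing")
        prev = x
        xs.append(x)
        ys.append(y)
    if len(xs) < 2:
        raise ParseError(f"{path}: need at least two data rows")
    return np.array(xs), np.array(ys)


def read_response_csv(
    path: str | Path,
    monitor_id: str | None = None,
    valid_range: tuple[float, float] | None = None,
) -> ResponseFunction:
    path = Path(path)
    e, r = _read_two_column(path, ["energy_MeV", "response"])
    return ResponseFunction(
        monitor_id=monitor_id or path.stem, energies=e, response=r, valid_range=valid_range
    )


def read_conversion_csv(path: str | Path) -> ConversionTable:
    e, h = _read_two_column(Path(path), ["energy_MeV", "h10_pSv_cm2"])
    return ConversionTable(energies=e, coefficients=h)


def read_lineal_csv(path: str | Path) -> LinealEnergySpectrum:
    path = Path(path)
    lows, highs, dose = [], [], []
    for lineno, fields in _rows(path, ["y_low_keV_um", "y_high_keV_um", "dose_Gy"]):
        lo, hi, d = _floats(path, lineno, fields, 3)
        if lows and not math.isclose(lo, highs[-1], rel_tol=1e-12):
            raise ParseError(f"{path}:{lineno}: bins must be contiguous and ascending")
        lows.append(lo)
        highs.append(hi)
        dose.append(d)
    if not lows:
        raise ParseError(f"{path}: no data rows")
    return LinealEnergySpectrum(np.array(lows + [highs[-1]]), np.array(dose))


def write_lineal_csv(spec: LinealEnergySpectrum, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write("y_low_keV_um,y_high_keV_um,dose_Gy\n")
        for lo, hi, d in zip(spec.y_edges[:-1], spec.y_edges[1:], spec.dose):
            fh.write(f"{_fmt(lo)},{_fmt(hi)},{_fmt(d)}\n")


def read_charges_csv(path: str | Path, interval: float = 0.1) -> ChargeSeries:
    path = Path(path)
    charges = []
    for lineno, fields in _rows(path, ["charge_C"]):
        (q,) = _floats(path, lineno, fields, 1)
        if q < 0:
            raise ParseError(f"{path}:{lineno}: negative charge")
        charges.append(q)
    if len(charges) < 2:
        raise ParseError(f"{path}: need at least two intervals")
    return ChargeSeries(np.array(charges), interval=interval)


def _parse_bool(path: Path, lineno: int, text: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ParseError(f"{path}:{lineno}: invalid boolean {text!r}")


def read_campaign_csv(path: str | Path) -> CampaignTable:
    path = Path(path)
    records = []
    seen: set[tuple[str, str]] = set()
    for lineno, fields in _rows(path, CAMPAIGN_COLUMNS):
        if len(fields) != len(CAMPAIGN_COLUMNS):
            raise ParseError(
                f"{path}:{lineno}: expected {len(CAMPAIGN_COLUMNS)} columns, got {len(fields)}"
            )
        irr, fs, rng, mod, rs, gap, pos, h10, unc = fields
        key = (irr, pos)
        if key in seen:
            raise ParseError(f"{path}:{lineno}: duplicate (irradiation, position) key {key}")
        seen.add(key)
        try:
            record = {
                "irradiation_id": irr,
                "field_size_cm2": float(fs),
                "range_cm": float(rng),
                "modulation_cm": float(mod),
                "range_shifter": _parse_bool(path, lineno, rs),
                "air_gap_cm": float("nan") if gap == "" else float(gap),
                "position": pos,
                "h10_uSv_per_Gy": float(h10),
                "rel_uncertainty": float(unc),
            }
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}:{lineno}: {exc}") from None
        if record["h10_uSv_per_Gy"] <= 0:
            raise ParseError(f"{path}:{lineno}: H*(10) must be positive")
        records.append(record)
    if not records:
        raise ParseError(f"{path}: no data rows")
    return CampaignTable(pd.DataFrame.from_records(records, columns=CAMPAIGN_COLUMNS))


def write_campaign_csv(table: CampaignTable, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(",".join(CAMPAIGN_COLUMNS) + "\n")
        for row in table.rows.itertuples(index=False):
            gap = "" if pd.isna(row.air_gap_cm) else _fmt(row.air_gap_cm)
            fh.write(
                ",".join(
                    [
                        str(row.irradiation_id),
                        _fmt(row.field_size_cm2),
                        _fmt(row.range_cm),
                        _fmt(row.modulation_cm),
                        "true" if row.range_shifter else "false",
                        gap,
                        str(row.position),
                        _fmt(row.h10_uSv_per_Gy),
                        _fmt(row.rel_uncertainty),
                    ]
                )
                + "\n"
            )


def load_monitor_registry(path: str | Path | None = None) -> dict[str, dict]:
    """Monitor registry: monitor_id -> {file, valid_range}."""
    if path is None:
        with resources.as_file(
            resources.files("pbsneutron.data") / "monitor_registry.yaml"
        ) as p:
            return load_monitor_registry(p)
    with open(path) as fh:
        registry = yaml.safe_load(fh)
    if not isinstance(registry, dict) or "monitors" not in registry:
        raise ParseError(f"{path}: registry must contain a 'monitors' mapping")
    return registry["monitors"]


def load_monitor(monitor_id: str, registry_path: str | Path | None = None) -> ResponseFunction:
    """Load a monitor response function by id from the registry."""
    registry = load_monitor_registry(registry_path)
    if monitor_id not in registry:
        raise KeyError(
            f"unknown monitor {monitor_id!r}; available: {sorted(registry)}"
        )
    entry = registry[monitor_id]
    valid_range = tuple(float(v) for v in entry["valid_range"])
    file_name = entry["file"]
    if registry_path is None:
        with resources.as_file(resources.files("pbsneutron.data") / file_name) as p:
            return read_response_csv(p, monitor_id=monitor_id, valid_range=valid_range)
    file_path = Path(registry_path).parent / file_name
    return read_response_csv(file_path, monitor_id=monitor_id, valid_range=valid_range)


def _plan_to_dict(plan: TreatmentPlan) -> dict:
    return {
        "field_size_cm2": plan.field_size_cm2,
        "range_cm": plan.range_cm,
        "modulation_cm": plan.modulation_cm,
        "range_shifter": plan.range_shifter,
        "air_gap_cm": plan.air_gap_cm,
        "rs_wet_cm": plan.rs_wet_cm,
    }


def save_model_yaml(model: ScalingModel, path: str | Path, provenance: dict | None = None) -> None:
    payload = {
        "reference_plan": _plan_to_dict(model.reference_plan),
        "rs_mode": model.rs_mode,
        "flat_factor": model.flat_factor,
        "coefficients": {
            pos: {
                "a0": c.a0,
                "c_range": c.c_range,
                "c_mod1": c.c_mod1,
                "c_mod2": c.c_mod2,
            }
            for pos, c in sorted(model.coefficients.items())
        },
        "positions": {
            label: {"distance_m": p.distance_m, "angle_deg": p.angle_deg}
            for label, p in sorted(model.positions.items())
        },
        "provenance": provenance or {},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_model_yaml(path: str | Path) -> ScalingModel:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    rp = payload["reference_plan"]
    reference_plan = TreatmentPlan(
        field_size_cm2=rp["field_size_cm2"],
        range_cm=rp["range_cm"],
        modulation_cm=rp["modulation_cm"],
        range_shifter=rp.get("range_shifter", False),
        air_gap_cm=rp.get("air_gap_cm"),
        rs_wet_cm=rp.get("rs_wet_cm", 3.1),
    )
    coefficients = {
        pos: PositionCoefficients(
            a0=c["a0"], c_range=c["c_range"], c_mod1=c["c_mod1"], c_mod2=c["c_mod2"]
        )
        for pos, c in payload["coefficients"].items()
    }
    positions = {
        label: Position(label, p["distance_m"], p["angle_deg"])
        for label, p in payload.get("positions", {}).items()
    }
    return ScalingModel(
        coefficients=coefficients,
        reference_plan=reference_plan,
        rs_mode=payload.get("rs_mode", "effective_range"),
        flat_factor=payload.get("flat_factor", 2.0),
        positions=positions,
    )
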