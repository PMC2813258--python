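"""Readers and writers for point sets, fields, fits and polylines.

All angle columns in files are radians; eccentricities are degrees and
cortical coordinates mm.  Schemas:

points (input):    ecc_deg, polar_rad [, area]
points (output):   ecc_deg, polar_rad, x_mm, y_mm, area
samples:           ecc_deg, polar_rad, x_mm, y_mm, area
field:             tidy, one row per grid node (see cartography)
polylines (JSON):  list of {kind, area, level|name, xy: [[x, y], ...]}

CSV floats are written round-trip exact (repr precision).
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import FitResult
from .params import ModelParams

__all__ = [
    "read_points", "write_points", "read_samples", "write_table",
    "write_polylines_json", "read_polylines_json", "write_fit_report",
]

_FLOAT_FMT = "%.17g"


def read_points(path: str | Path, require_area: bool = False) -> pd.DataFrame:
    """Read a visual-field point set from CSV or JSON."""
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        df = pd.read_csv(path, float_precision="round_trip")
    need = {"ecc_deg", "polar_rad"} | ({"area"} if require_area else set())
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if not np.all(np.isfinite(df["ecc_deg"])) or np.any(df["ecc_deg"] < 0):
        raise ValueError(f"{path}: ecc_deg must be finite and >= 0")
    return df


def write_points(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records")))
    else:
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Read retinotopy samples (ecc_deg, polar_rad, x_mm, y_mm, area)."""
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"ecc_deg", "polar_rad", "x_mm", "y_mm", "area"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any tidy table as CSV (or JSON records by extension)."""
    write_points(df, path)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_polylines_json(polylines: list[dict], path: str | Path) -> None:
    Path(path).write_text(json.dumps(polylines, default=_jsonify))


def read_polylines_json(path: str | Path) -> list[dict]:
    data = json.loads(Path(path).read_text())
    for d in data:
        d["xy"] = np.asarray(d["xy"], dtype=float)
    return data


def write_fit_report(result: FitResult, path: str | Path) -> None:
    """FitResult as a JSON report (params, diagnostics, summary text)."""
    d = dataclasses.asdict(result)
    d["params"] = result.params.to_dict()
    d["stderr"] = dict(result.stderr)
    d["summary"] = result.summary()
    Path(path).write_text(json.dumps(d, indent=2, default=_jsonify))
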