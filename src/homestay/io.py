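"""Readers and writers for the pipeline's plain-CSV interchange formats.

Schemas
-------
gps.csv      participant,timestamp,lat,lon
ema.csv      participant,timestamp,pa,na
traits.csv   participant,sias,dass_dep

Timestamps are ISO 8601 strings and must carry a UTC offset; all window
logic downstream runs in a configured local timezone, so ambiguous naive
times are rejected at the door.  Readers validate every row and raise a
single summary error listing each offending row and field.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "InputError", "SchemaError", "EmptyInputError", "RowValidationError",
    "read_gps", "read_ema", "read_traits",
    "write_gps", "write_ema", "write_traits",
    "write_run_metadata",
]


class InputError(ValueError):
    """Base class for input-file problems."""


class SchemaError(InputError):
    """A required column is missing."""


class EmptyInputError(InputError):
    """The file has a header but no data rows."""


class RowValidationError(InputError):
    """One or more rows violate the schema invariants."""

    def __init__(self, path: str | Path, errors: list[str]):
        self.errors = errors
        shown = "; ".join(errors[:20])
        more = f" (+{len(errors) - 20} more)" if len(errors) > 20 else ""
        super().__init__(f"{path}: {len(errors)} invalid row(s): {shown}{more}")


_OFFSET_RE = re.compile(r"(?:Z|[+-]\d{2}:?\d{2})\s*$")


def _load(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    df = pd.read_csv(path, dtype={"participant": str})
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")
    if len(df) == 0:
        raise EmptyInputError(f"{path}: file contains no data rows")
    return df[columns].copy()


def _parse_timestamps(df: pd.DataFrame, errors: list[str]) -> pd.Series:
    raw = df["timestamp"].astype(str)
    has_offset = raw.str.contains(_OFFSET_RE)
    parsed = pd.to_datetime(raw, errors="coerce", utc=True, format="ISO8601")
    for idx in df.index[parsed.isna()]:
        errors.append(f"row {idx + 2}: unparseable timestamp {raw[idx]!r}")
    for idx in df.index[parsed.notna() & ~has_offset]:
        errors.append(f"row {idx + 2}: timestamp {raw[idx]!r} lacks a UTC offset")
    return parsed


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float,
                 errors: list[str]) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    for idx in df.index[vals.isna()]:
        errors.append(f"row {idx + 2}: non-numeric {col} {df[col][idx]!r}")
    bad = vals.notna() & ((vals < lo) | (vals > hi))
    for idx in df.index[bad]:
        errors.append(f"row {idx + 2}: {col}={vals[idx]} outside [{lo}, {hi}]")
    return vals


def _finish(df: pd.DataFrame, path: str | Path, errors: list[str],
            sort_time: bool = True) -> pd.DataFrame:
    if errors:
        raise RowValidationError(path, errors)
    keys = ["participant", "time"] if sort_time else ["participant"]
    return df.sort_values(keys, kind="mergesort").reset_index(drop=True)


def read_gps(path: str | Path) -> pd.DataFrame:
    """Read GPS fixes; returns participant, time (tz-aware UTC), lat, lon."""
    df = _load(path, ["participant", "timestamp", "lat", "lon"])
    errors: list[str] = []
    time = _parse_timestamps(df, errors)
    lat = _check_range(df, "lat", -90.0, 90.0, errors)
    lon = _check_range(df, "lon", -180.0, 180.0, errors)
    out = pd.DataFrame({"participant": df["participant"], "time": time,
                        "lat": lat, "lon": lon})
    return _finish(out, path, errors)


def read_ema(path: str | Path) -> pd.DataFrame:
    """Read affect observations; returns participant, time, pa, na."""
    df = _load(path, ["participant", "timestamp", "pa", "na"])
    errors: list[str] = []
    time = _parse_timestamps(df, errors)
    pa = _check_range(df, "pa", 0.0, 100.0, errors)
    na = _check_range(df, "na", 0.0, 100.0, errors)
    out = pd.DataFrame({"participant": df["participant"], "time": time,
                        "pa": pa, "na": na})
    return _finish(out, path, errors)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Read baseline trait totals; returns participant, sias, dass_dep."""
    df = _load(path, ["participant", "sias", "dass_dep"])
    errors: list[str] = []
    sias = _check_range(df, "sias", 0.0, 80.0, errors)
    dass = _check_range(df, "dass_dep", 0.0, 21.0, errors)
    out = pd.DataFrame({"participant": df["participant"], "sias": sias,
                        "dass_dep": dass})
    for idx in out.index[out["participant"].duplicated()]:
        errors.append(f"row {idx + 2}: duplicate participant {out['participant'][idx]!r}")
    return _finish(out, path, errors, sort_time=False)


def _iso(series: pd.Series) -> pd.Series:
    return series.map(lambda t: t.isoformat())


def write_gps(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"participant": df["participant"],
                        "timestamp": _iso(df["time"]),
                        "lat": df["lat"], "lon": df["lon"]})
    out.to_csv(path, index=False)


def write_ema(df: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame({"participant": df["participant"],
                        "timestamp": _iso(df["time"]),
                        "pa": df["pa"], "na": df["na"]})
    out.to_csv(path, index=False)


def write_traits(df: pd.DataFrame, path: str | Path) -> None:
    df[["participant", "sias", "dass_dep"]].to_csv(path, index=False)


def write_run_metadata(out_dir: str | Path, stage: str,
                       config: dict[str, Any], **extra: Any) -> Path:
    """Write a machine-readable sidecar describing one pipeline stage run."""
    import homestay

    meta = {
        "stage": stage,
        "package_version": homestay.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": config,
    }
    meta.update(extra)
    path = Path(out_dir) / f"run_{stage}.json"
    path.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n")
    return path
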