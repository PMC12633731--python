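"""Tabular I/O with schema validation.

All pipeline inputs and outputs are plain CSV with documented columns:

- trajectory:   trial, frame, time_s, landmark, x, y, z
- cycles:       trial, behaviour, t_start, t_mid, t_end
- signal:       trial, fish, muscle, time_s, value
- observations: fish, behaviour, muscle, scope, variable, value
- angles:       variable, muscle, behaviour, angle_deg
- fluorescence: fish, size_class, treatment, muscle, pct_fin_length,
                cell_intensity, background

Readers validate against the schema and fail naming the offending column
and row; a write -> read round trip is the identity on all typed fields.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "read_table", "write_table", "SchemaError"]


class SchemaError(ValueError):
    pass


def _angle_ok(s: pd.Series) -> pd.Series:
    return (s >= 0) & (s < 360)


SCHEMAS: dict[str, dict] = {
    "trajectory": {
        "columns": {"trial": str, "frame": int, "time_s": float,
                    "landmark": str, "x": float, "y": float, "z": float},
        "checks": {},
    },
    "cycles": {
        "columns": {"trial": str, "behaviour": str, "t_start": float,
                    "t_mid": float, "t_end": float},
        "checks": {"t_mid": lambda df: df["t_start"] < df["t_mid"],
                   "t_end": lambda df: df["t_mid"] < df["t_end"]},
    },
    "signal": {
        "columns": {"trial": str, "fish": str, "muscle": str,
                    "time_s": float, "value": float},
        "checks": {},
    },
    "observations": {
        "columns": {"fish": str, "behaviour": str, "muscle": str,
                    "scope": str, "variable": str, "value": float},
        "checks": {},
    },
    "angles": {
        "columns": {"variable": str, "muscle": str, "behaviour": str,
                    "angle_deg": float},
        "checks": {"angle_deg": lambda df: _angle_ok(df["angle_deg"])},
    },
    "fluorescence": {
        "columns": {"fish": str, "size_class": str, "treatment": str,
                    "muscle": str, "pct_fin_length": float,
                    "cell_intensity": float, "background": float},
        "checks": {"pct_fin_length":
                   lambda df: df["pct_fin_length"].between(0, 100)},
    },
}


def _validate(df: pd.DataFrame, kind: str) -> pd.DataFrame:
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    spec = SCHEMAS[kind]
    for col, typ in spec["columns"].items():
        if col not in df.columns:
            raise SchemaError(f"{kind}: missing column {col!r}")
    df = df[list(spec["columns"])].copy()
    for col, typ in spec["columns"].items():
        try:
            if typ is float:
                df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
            elif typ is int:
                df[col] = pd.to_numeric(df[col], errors="raise").astype(int)
            else:
                df[col] = df[col].astype(str)
        except (ValueError, TypeError) as e:
            raise SchemaError(f"{kind}: column {col!r} failed type "
                              f"{typ.__name__}: {e}") from e
        if typ is float and not np.all(np.isfinite(df[col])):
            row = int(np.flatnonzero(~np.isfinite(df[col]))[0])
            raise SchemaError(f"{kind}: non-finite value in {col!r} row {row}")
    for col, check in spec["checks"].items():
        ok = check(df) if len(df) else pd.Series(dtype=bool)
        if len(df) and not ok.all():
            row = int(np.flatnonzero(~ok.values)[0])
            raise SchemaError(f"{kind}: constraint on {col!r} violated at "
                              f"row {row} (value {df.iloc[row][col]!r})")
    return df


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read and validate a typed CSV table (empty files give empty frames)."""
    df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame({c: pd.Series(dtype="float64" if t is float else
                                          "int64" if t is int else "object")
                             for c, t in SCHEMAS[kind]["columns"].items()})
    return _validate(df, kind)


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> Path:
    """Validate and write a typed CSV table."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = _validate(df, kind) if len(df) else df
    out.to_csv(path, index=False)
    return path
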