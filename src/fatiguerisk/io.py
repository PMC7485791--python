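"""Typed CSV I/O for every table the pipeline reads or writes.

All files are UTF-8 CSV with '.' decimals, ISO-8601 dates and a fixed,
schema-checked column set.  Schema violations are reported by column name;
unparseable cells are reported with their line number.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table"]

SCHEMA_VERSION = "1"


class SchemaError(ValueError):
    """A table does not match its declared schema."""


#: column -> dtype ("str", "int", "float", "bool") per table
SCHEMAS: Dict[str, Dict[str, str]] = {
    "drivers": {"driver_id": "str", "age": "int", "sex": "str"},
    "rri": {
        "driver_id": "str",
        "date": "str",
        "condition": "str",
        "beat_index": "int",
        "rri_ms": "float",
    },
    "vas": {"driver_id": "str", "date": "str", "condition": "str", "vas": "float"},
    "events": {
        "driver_id": "str",
        "date": "str",
        "event_id": "str",
        "start_time": "str",
        "sample_index": "int",
        "speed_kmh": "float",
    },
    "annotations": {
        "driver_id": "str",
        "date": "str",
        "event_id": "str",
        "label": "int",
    },
    "cohort": {
        "driver_id": "str",
        "date": "str",
        "age": "float",
        "vas_pre": "float",
        "vas_post": "float",
        "lf_score_pre": "float",
        "lf_score_post": "float",
        "lf_hf_pre": "float",
        "lf_hf_post": "float",
        "wt_hours": "float",
        "n_events": "int",
        "R": "int",
        "r_1hr": "float",
        "included": "bool",
    },
    "hrv": {
        "driver_id": "str",
        "date": "str",
        "condition": "str",
        "n_beats": "int",
        "accepted": "bool",
        "lf_power": "float",
        "hf_power": "float",
        "lf_hf": "float",
        "rri_average": "float",
        "lf_score": "float",
    },
    "features": {
        "driver_id": "str",
        "date": "str",
        "event_id": "str",
        "duration_s": "float",
        "max_speed_kmh": "float",
        "min_speed_kmh": "float",
        "avg_speed_kmh": "float",
        "speed_sd_kmh": "float",
        "max_decel_kmh_s": "float",
    },
    "predictions": {
        "driver_id": "str",
        "date": "str",
        "event_id": "str",
        "prediction": "int",
    },
    "daily": {
        "driver_id": "str",
        "date": "str",
        "R": "int",
        "wt_hours": "float",
        "r_1hr": "float",
        "included": "bool",
        "n_events": "int",
    },
    "truth_recordings": {
        "driver_id": "str",
        "date": "str",
        "condition": "str",
        "lf_power_true": "float",
        "hf_power_true": "float",
        "mean_rri_ms": "float",
        "lf_score_true": "float",
    },
    "truth_events": {
        "driver_id": "str",
        "date": "str",
        "event_id": "str",
        "rule_label": "int",
    },
    "truth_days": {
        "driver_id": "str",
        "date": "str",
        "risk_rate_per_hr_true": "float",
        "lf_score_post_prev_true": "float",
    },
    "norms": {"age_lo": "float", "age_hi": "float", "mu_lf": "float", "sigma_lf": "float"},
}

_CASTS = {
    "str": lambda s: s.astype(str),
    "int": lambda s: pd.to_numeric(s, errors="coerce").astype("Int64"),
    "float": lambda s: pd.to_numeric(s, errors="coerce"),
    "bool": lambda s: s.map(
        {"True": True, "False": False, "true": True, "false": False,
         "1": True, "0": False, True: True, False: False}
    ),
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema.

    Raises :class:`SchemaError` naming the offending column when required
    columns are missing or unexpected columns are present, and a row-level
    error (with the 1-based file line number) for unparseable cells.
    An empty file with a valid header yields an empty, correctly typed frame.
    """
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in spec if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    extra = [c for c in raw.columns if c not in spec]
    if extra:
        raise SchemaError(f"{path}: unexpected column(s): {', '.join(extra)}")
    out = {}
    for col, kind in spec.items():
        raw_col = raw[col].replace("", np.nan) if kind != "str" else raw[col]
        cast = _CASTS[kind](raw_col)
        if kind in ("int", "float", "bool"):
            bad = cast.isna() & raw_col.notna()
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
                raise SchemaError(
                    f"{path}: cannot parse column '{col}' as {kind} at line {line}: "
                    f"{raw[col].iloc[line - 2]!r}"
                )
        if kind == "int":
            cast = cast.astype("Int64")
        out[col] = cast
    df = pd.DataFrame(out)
    if "included" in df.columns:
        df["included"] = df["included"].astype(bool)
    if "accepted" in df.columns:
        df["accepted"] = df["accepted"].astype(bool)
    return df


def write_table(df: pd.DataFrame, path, schema: str) -> None:
    """Write a CSV in the canonical column order of a named schema."""
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"cannot write {schema}: missing column(s): {', '.join(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.loc[:, list(spec)].to_csv(path, index=False)
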