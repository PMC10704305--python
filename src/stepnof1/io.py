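"""Long-format CSV interchange for person-day datasets.

One row per participant-day, deterministic column order, empty fields
for missing values, and a JSON sidecar carrying provenance (seed and
config hash) so a written dataset can be traced to its generator call.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import DATA_COLUMNS, LongDataset

__all__ = ["read_dataset", "write_dataset", "sidecar_path"]

_INT_COLS = [
    "day_index", "weekday", "period_index",
    "dmi_available", "bf_suggested", "washout", "control", "leadout",
    "dmi_used", "bf_used",
]
_NULLABLE_INT_COLS = ["steps", "se_morning", "mot_morning", "mot_evening",
                      "barriers", "pain"]
_RANGES = {
    "weekday": (1, 7),
    "steps": (0, None),
    "se_morning": (1, 9),
    "mot_morning": (1, 9),
    "mot_evening": (1, 9),
    "barriers": (1, 9),
    "pain": (0, 2),
}


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".meta.json")


def write_dataset(dataset: LongDataset, path) -> Path:
    """Write a dataset to CSV (plus a .meta.json sidecar); byte-deterministic."""
    dataset.validate()
    path = Path(path)
    df = dataset.data.copy()
    for col in _INT_COLS:
        df[col] = df[col].astype(int)
    for col in _NULLABLE_INT_COLS:
        df[col] = df[col].round().astype("Int64")
    df = df[DATA_COLUMNS]
    df.to_csv(path, index=False, lineterminator="\n")
    meta = {"seed": dataset.seed, "config_hash": dataset.config_hash,
            "n_rows": len(df), "columns": DATA_COLUMNS}
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_dataset(path) -> LongDataset:
    """Read and validate a long-format CSV; errors name offending rows.

    Row numbers in error messages are 1-based data rows (header = row 0).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "condition": str},
                     keep_default_na=True)
    df["condition"] = df["condition"].fillna("")
    if list(df.columns) != DATA_COLUMNS:
        raise ValueError(
            f"header mismatch: expected {DATA_COLUMNS}, got {list(df.columns)}")
    errors: list[str] = []
    for col in _INT_COLS:
        if df[col].isna().any():
            rows = (df.index[df[col].isna()] + 1).tolist()[:5]
            errors.append(f"column {col}: missing values at rows {rows}")
    for col in _NULLABLE_INT_COLS:
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    for col, (lo, hi) in _RANGES.items():
        vals = df[col]
        bad = pd.Series(False, index=df.index)
        if lo is not None:
            bad |= vals < lo
        if hi is not None:
            bad |= vals > hi
        if bad.any():
            rows = (df.index[bad] + 1).tolist()[:5]
            errors.append(f"column {col}: out-of-range values at rows {rows}")
    dup = df.duplicated(["participant_id", "day_index"])
    if dup.any():
        rows = (df.index[dup] + 1).tolist()[:5]
        errors.append(f"duplicate (participant_id, day_index) at rows {rows}")
    if errors:
        raise ValueError(f"invalid dataset {path.name}: " + "; ".join(errors))

    meta_file = sidecar_path(path)
    seed, config_hash = -1, ""
    if meta_file.exists():
        meta = json.loads(meta_file.read_text())
        seed = int(meta.get("seed", -1))
        config_hash = str(meta.get("config_hash", ""))
    ds = LongDataset(data=df, seed=seed, config_hash=config_hash)
    ds.validate()
    return ds
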