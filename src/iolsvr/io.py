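"""Canonical cohort CSV reading and writing.

One dialect everywhere: UTF-8, comma-separated, header row, '.' decimal.
Columns, in order: eye_id, axl_mm, cr_mm, acd_mm, lt_mm, wtw_mm,
a_constant, iol_power_d, mrse_d, iol_model, haptic_type.  Reads are
validated row by row so malformed values are reported with their file line
number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import COHORT_COLUMNS
from .exceptions import SchemaError

NUMERIC_COLUMNS = [
    "axl_mm", "cr_mm", "acd_mm", "lt_mm", "wtw_mm",
    "a_constant", "iol_power_d", "mrse_d",
]

OPTIONAL_APPENDED = ["srkt_pred_d", "emme_power_d", "refined_pred_d"]


def read_cohort(path) -> pd.DataFrame:
    """Read a canonical cohort CSV; lossless and order-preserving."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {missing}")
    out = df.copy()
    for col in NUMERIC_COLUMNS + [c for c in OPTIONAL_APPENDED if c in df.columns]:
        converted = pd.to_numeric(df[col].replace("", np.nan), errors="coerce")
        bad = converted.isna() & (df[col] != "")
        if bad.any():
            # +2: one for the header row, one for 1-based numbering
            line = int(np.flatnonzero(bad)[0]) + 2
            raise SchemaError(
                f"{path}: non-numeric value {df[col][bad].iloc[0]!r} in "
                f"column {col!r} on line {line}"
            )
        out[col] = converted
    return out


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the canonical dialect (full float precision)."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"refusing to write cohort lacking column(s): {missing}")
    ordered = COHORT_COLUMNS + [
        c for c in df.columns if c not in COHORT_COLUMNS
    ]
    df[ordered].to_csv(path, index=False, encoding="utf-8", float_format=None)
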