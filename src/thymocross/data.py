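"""Tidy count-table input/output.

The package-wide dataset dialect is a tidy table with columns
``day, cell_type, replicate, count`` (days as integers, counts as floats,
UTF-8 comma-separated CSV with a header row).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["COLUMNS", "validate_counts", "load_counts", "save_counts"]

COLUMNS = ("day", "cell_type", "replicate", "count")


def validate_counts(df: pd.DataFrame, require_positive: bool = True) -> pd.DataFrame:
    """Check the tidy count-table contract and return a normalized copy."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"count table is missing column(s) {missing}")
    out = df.loc[:, list(COLUMNS)].copy()
    out["day"] = out["day"].astype(float)
    out["cell_type"] = out["cell_type"].astype(str)
    out["replicate"] = out["replicate"].astype(int)
    out["count"] = out["count"].astype(float)
    if out["day"].min() < 0:
        raise ValueError("days must be >= 0")
    if not np.all(np.isfinite(out["count"])):
        raise ValueError("counts must be finite")
    if require_positive and (out["count"] <= 0).any():
        bad = out.loc[out["count"] <= 0].head()
        raise ValueError(
            f"counts must be strictly positive (log-scale residuals); offending rows:\n{bad}")
    return out


def load_counts(path, require_positive: bool = True) -> pd.DataFrame:
    return validate_counts(pd.read_csv(path), require_positive=require_positive)


def save_counts(df: pd.DataFrame, path) -> None:
    validate_counts(df).to_csv(path, index=False)
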