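"""Long-table CSV schemas shared by the synthetic and real-data paths.

The pooled-SNR table (subject_id, phase, condition, snr, spai) is the sole
input of the statistics stages, so a user can substitute real data by
supplying CSVs with these columns.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CONDITIONS, PHASES

logger = logging.getLogger(__name__)

SNR_COLUMNS = ["subject_id", "phase", "condition", "snr", "spai"]
RATING_COLUMNS = ["subject_id", "phase", "condition", "scale", "value", "spai"]


class SchemaError(ValueError):
    pass


def _check_schema(df: pd.DataFrame, required: list[str], name: str) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("%s: ignoring extra column(s) %s", name, extra)
    return df[required].copy()


def _check_values(df: pd.DataFrame, name: str, numeric: list[str]) -> None:
    bad_phase = ~df["phase"].isin(PHASES)
    if bad_phase.any():
        rows = df.index[bad_phase].tolist()[:5]
        raise SchemaError(f"{name}: unknown phase at row(s) {rows}")
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        rows = df.index[bad_cond].tolist()[:5]
        raise SchemaError(f"{name}: unknown condition at row(s) {rows}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals)
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise SchemaError(f"{name}: non-numeric {col!r} at row(s) {rows}")
        df[col] = vals


def load_snr_table(path: str | Path) -> pd.DataFrame:
    df = _check_schema(pd.read_csv(path), SNR_COLUMNS, str(path))
    _check_values(df, str(path), ["snr", "spai"])
    if (df["snr"] <= 0).any():
        rows = df.index[df["snr"] <= 0].tolist()[:5]
        raise SchemaError(f"{path}: non-positive snr at row(s) {rows}")
    return df


def load_ratings_table(path: str | Path) -> pd.DataFrame:
    df = _check_schema(pd.read_csv(path), RATING_COLUMNS, str(path))
    _check_values(df, str(path), ["value", "spai"])
    if ((df["phase"] == "habituation") & (df["scale"] == "us_expectancy")).any():
        raise SchemaError(f"{path}: us_expectancy rows present for habituation")
    return df


def load_real_data(snr_csv: str | Path, ratings_csv: str | Path | None = None):
    """Load user-supplied tables for the statistics stages."""
    snr = load_snr_table(snr_csv)
    ratings = load_ratings_table(ratings_csv) if ratings_csv else None
    return snr, ratings


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    """Deterministic CSV output (fixed float format, no index)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path
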