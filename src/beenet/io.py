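"""Validated CSV input/output for the pipeline's tables.

All tables are UTF-8 CSVs with a header row.  Readers check the schema
column by column, coerce types, and report offending row numbers; writers
round-trip through the same schemas.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .abundance import SWEEP_COLUMNS
from .network import POLLEN_COLUMNS, PLOT_TYPES, InteractionMatrix, ValidationError

logger = logging.getLogger(__name__)

FLOWER_COLUMNS = ("plot_id", "plot_type", "survey_round", "plant_species",
                  "flower_count")

_INT_COLUMNS = {"survey_round", "grain_count", "count", "flower_count"}


def _read_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing column(s) {missing}")
    df = df[list(columns)]
    for col in columns:
        if col not in _INT_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() | (coerced != coerced.round())
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]  # 1-based incl. header
            raise ValidationError(
                f"{path.name}: non-integer {col!r} at file row(s) {rows}"
            )
        df[col] = coerced.astype(int)
    if "plot_type" in columns:
        bad = ~df["plot_type"].isin(PLOT_TYPES)
        if bad.any():
            rows = (df.index[bad] + 2).tolist()[:5]
            raise ValidationError(
                f"{path.name}: plot_type not in {PLOT_TYPES} at row(s) {rows}"
            )
    return df


def read_pollen_records(path: str | Path) -> pd.DataFrame:
    """Read and validate a pollen-load record table.

    Duplicate (individual_id, plant_species) pairs and negative grain counts
    are rejected with the offending file rows named.
    """
    df = _read_table(path, POLLEN_COLUMNS)
    if (df["grain_count"] < 0).any():
        rows = (df.index[df["grain_count"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"negative grain_count at file row(s) {rows}")
    dup = df.duplicated(subset=["individual_id", "plant_species"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValidationError(
            f"duplicate (individual_id, plant_species) at file row(s) {rows}"
        )
    return df


def read_sweep_counts(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, SWEEP_COLUMNS)
    if (df["count"] < 0).any():
        rows = (df.index[df["count"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"negative count at file row(s) {rows}")
    return df


def read_flower_surveys(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, FLOWER_COLUMNS)
    if (df["flower_count"] < 0).any():
        rows = (df.index[df["flower_count"] < 0] + 2).tolist()[:5]
        raise ValidationError(f"negative flower_count at file row(s) {rows}")
    return df


def write_network(net: InteractionMatrix, path: str | Path) -> None:
    """Write a network matrix CSV plus a ``*.specimens.csv`` sidecar."""
    path = Path(path)
    counts = net.counts.copy()
    counts.index.name = "bee_species"
    counts.to_csv(path)
    sidecar = path.with_suffix(".specimens.csv")
    spec = net.specimens.rename("specimens").to_frame()
    spec.index.name = "bee_species"
    spec.to_csv(sidecar)


def read_network(path: str | Path, plot_id: str, plot_type: str) -> InteractionMatrix:
    path = Path(path)
    counts = pd.read_csv(path, index_col="bee_species")
    counts.columns.name = "plant_species"
    spec = pd.read_csv(path.with_suffix(".specimens.csv"), index_col="bee_species")
    return InteractionMatrix(plot_id, plot_type, counts, spec["specimens"])
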