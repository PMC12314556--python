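"""Tabular I/O for per-cell tables, well-level feature matrices and growth tracks.

Header contracts
----------------
All tables are plain CSV with dot decimal separators. Metadata columns share
the reserved prefix ``Metadata_`` (the convention of standard Cell Painting
profile exports); every other column is a measurement.

* Cell tables require: ``Metadata_Plate, Metadata_Well, Metadata_Genotype,
  Metadata_Treatment, Metadata_Concentration, Metadata_Replicate,
  nuclear_intensity, cytoplasmic_intensity, contact_percent``.
* Feature matrices require the same metadata columns plus ``Metadata_Family``
  and at least one feature column; feature names must be unique.
* Growth tables require the metadata columns plus ``time_h`` and a value
  column (``area`` for spheroids, ``confluency`` for 2D growth).

Rows with missing nuclear or cytoplasmic values are flagged in a boolean
``flag_missing_intensity`` column, never silently dropped.
"""

from __future__ import annotations

import csv
from pathlib import Path

import pandas as pd

from .exceptions import EmptyInputError, SchemaError

METADATA_PREFIX = "Metadata_"

CELL_METADATA = [
    "Metadata_Plate",
    "Metadata_Well",
    "Metadata_Genotype",
    "Metadata_Treatment",
    "Metadata_Concentration",
    "Metadata_Replicate",
]
CELL_MEASURES = ["nuclear_intensity", "cytoplasmic_intensity", "contact_percent"]
CELL_REQUIRED = CELL_METADATA + CELL_MEASURES

MATRIX_METADATA = CELL_METADATA + ["Metadata_Family"]

GROWTH_REQUIRED = CELL_METADATA + ["Metadata_Family", "time_h"]


def feature_columns(df: pd.DataFrame) -> list[str]:
    """Names of non-metadata (feature/measurement) columns, in table order."""
    return [c for c in df.columns if not c.startswith(METADATA_PREFIX)]


def metadata_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith(METADATA_PREFIX)]


def well_ids(df: pd.DataFrame) -> pd.Series:
    """Unique well identifiers ``plate:well``."""
    return df["Metadata_Plate"].astype(str) + ":" + df["Metadata_Well"].astype(str)


def _read_header(path) -> list[str]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            return next(reader)
        except StopIteration:
            raise EmptyInputError(f"{path}: file is empty")


def _check_columns(header: list[str], required, path) -> None:
    for col in required:
        if col not in header:
            raise SchemaError(f"{path}: missing required column '{col}'")


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell table, flagging rows with missing intensities."""
    path = Path(path)
    header = _read_header(path)
    _check_columns(header, CELL_REQUIRED, path)
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    df["flag_missing_intensity"] = (
        df["nuclear_intensity"].isna() | df["cytoplasmic_intensity"].isna()
    )
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_feature_matrix(path) -> pd.DataFrame:
    """Read a well × feature matrix; duplicate feature names are a schema error."""
    path = Path(path)
    header = _read_header(path)
    _check_columns(header, MATRIX_METADATA, path)
    dupes = sorted({c for c in header if header.count(c) > 1})
    if dupes:
        raise SchemaError(f"{path}: duplicate feature column(s): {', '.join(dupes)}")
    n_features = sum(1 for c in header if not c.startswith(METADATA_PREFIX))
    if n_features == 0:
        raise SchemaError(f"{path}: no feature columns")
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_growth_table(path, value_col: str = "area") -> pd.DataFrame:
    path = Path(path)
    header = _read_header(path)
    _check_columns(header, GROWTH_REQUIRED + [value_col], path)
    df = pd.read_csv(path)
    if df.empty:
        raise EmptyInputError(f"{path}: no data rows")
    return df


def write_growth_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
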