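"""Delimited-text I/O with schema validation and provenance headers.

Matrices are genes-as-rows TSV/CSV (delimiter chosen by extension) with the
gene id in the first column; subject tables follow a fixed column schema.
Writers can prepend ``#``-prefixed provenance lines (config hash, seed,
stage), which readers skip.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional

import pandas as pd

from .preprocess import DataError, ExpressionMatrix

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_subjects",
    "write_table",
    "SUBJECT_COLUMNS",
    "ParseError",
]

#: Required subject-table columns; age/sex/ph/pmi/zt are optional extras.
SUBJECT_COLUMNS = ["subject_id", "cohort", "death_datetime", "tz", "lat", "lon", "elev_m", "site"]


class ParseError(DataError):
    """Malformed delimited-text input, with file/line context."""


def _sep(path: str) -> str:
    return "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"


def read_matrix(path: str, stage: str = "log2") -> ExpressionMatrix:
    """Read a genes x subjects matrix (first column = gene_id)."""
    try:
        df = pd.read_csv(path, sep=_sep(path), index_col=0, comment="#")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.index.isna().any():
        raise ParseError(f"{path}: missing gene id")
    bad = df.columns[df.isna().all()]
    if len(bad):
        raise ParseError(f"{path}: empty columns {bad.tolist()}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric values in columns {non_numeric[:5]}")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return ExpressionMatrix(df, stage)


def write_matrix(
    matrix: ExpressionMatrix, path: str, provenance: Optional[Iterable[str]] = None
) -> None:
    """Write a matrix as delimited text, rejecting ids that embed the delimiter."""
    sep = _sep(path)
    for gid in matrix.data.index.astype(str):
        if sep in gid or "\n" in gid:
            raise DataError(f"gene id {gid!r} contains the delimiter; refusing to write")
    for sid in matrix.data.columns.astype(str):
        if sep in sid or "\n" in sid:
            raise DataError(f"subject id {sid!r} contains the delimiter; refusing to write")
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        matrix.data.to_csv(fh, sep=sep, index_label="gene_id", lineterminator="\n")


def read_subjects(path: str) -> pd.DataFrame:
    """Read and validate a subject metadata table."""
    try:
        df = pd.read_csv(path, sep=_sep(path), comment="#", dtype={"subject_id": str})
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in SUBJECT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: subject table missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ParseError(f"{path}: duplicate subject ids {dups[:5]}")
    for col, line in (("lat", None), ("lon", None), ("elev_m", None)):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            rownum = int(bad.idxmax()) + 2  # 1-based + header line
            raise ParseError(f"{path}: non-numeric {col!r} at line {rownum}")
        df[col] = pd.to_numeric(df[col])
    return df


def write_table(
    df: pd.DataFrame, path: str, provenance: Optional[Iterable[str]] = None
) -> None:
    """Write any result table as delimited text with optional provenance header."""
    os.makedirs(os.path.dirname(path) or ".", exist_ok=True)
    with open(path, "w") as fh:
        for line in provenance or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=_sep(path), index=False, lineterminator="\n")
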