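"""Readers and writers for the pipeline's tabular formats.

Expression and centroid matrices travel as TSV/CSV with a header row of
sample (or subtype) IDs and gene IDs in the first column; clinical tables as
CSV with one row per patient.  All validation errors name the offending row
or column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

BOR_DOMAIN = {"CR", "PR", "SD", "PD", "NE"}
ARM_DOMAIN = {"abemaciclib", "erlotinib"}

REQUIRED_CLINICAL_COLUMNS = (
    "patient_id",
    "arm",
    "bor",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
)


def _sep_for(path: str | Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "CSV" if str(path).lower().endswith(".csv") else "TSV"
    if fmt.upper() not in ("TSV", "CSV"):
        raise ValueError(f"unknown format {fmt!r}")
    return "," if fmt.upper() == "CSV" else "\t"


def read_expression(path: str | Path, fmt: str | None = None) -> tuple[pd.DataFrame, bool]:
    """Read a gene×sample matrix; returns (matrix, is_counts).

    A matrix is tagged as counts when every cell is a non-negative integer.
    Duplicate gene/sample IDs and non-numeric cells raise with the offending
    identifier.
    """
    df = pd.read_csv(path, sep=_sep_for(path, fmt), index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
    if df.columns.duplicated().any():
        dupes = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in column {col!r}, row {bad.index[0]!r}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        raise ValueError(f"missing value in column {col!r}")
    values = df.to_numpy()
    is_counts = bool(np.all(values >= 0) and np.all(values == np.round(values)))
    return df, is_counts


def write_expression(df: pd.DataFrame, path: str | Path, fmt: str | None = None) -> None:
    df.to_csv(path, sep=_sep_for(path, fmt), index_label="gene_id")


def read_centroids(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene×subtype centroid table (TSV by default)."""
    df, _ = read_expression(path, fmt)
    if df.shape[1] < 2:
        raise ValueError("centroid table needs at least 2 subtype columns")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate a per-patient clinical CSV.

    Categorical fields are checked against their domains; a PFS time
    exceeding the OS time is logged as a warning but the record is retained.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dupes = df["patient_id"][df["patient_id"].duplicated()].tolist()
        raise ValueError(f"duplicate patient IDs: {dupes[:5]}")
    for i, row in df.iterrows():
        if row["bor"] not in BOR_DOMAIN:
            raise ValueError(f"row {i} (patient {row['patient_id']}): unknown BOR {row['bor']!r}")
        if row["arm"] not in ARM_DOMAIN:
            raise ValueError(f"row {i} (patient {row['patient_id']}): unknown arm {row['arm']!r}")
        for col in ("os_months", "pfs_months"):
            if not np.isfinite(row[col]) or row[col] < 0:
                raise ValueError(
                    f"row {i} (patient {row['patient_id']}): invalid {col} {row[col]!r}"
                )
        for col in ("os_event", "pfs_event"):
            if row[col] not in (0, 1):
                raise ValueError(
                    f"row {i} (patient {row['patient_id']}): {col} must be 0/1"
                )
    inconsistent = df["pfs_months"] > df["os_months"]
    if inconsistent.any():
        import logging

        logging.getLogger(__name__).warning(
            "%d records have pfs_months > os_months (retained)", int(inconsistent.sum())
        )
    return df


def write_clinical(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.Series:
    """Two-column TSV (sample_id, subtype) -> label series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="subtype")


def write_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample_id": labels.index, "subtype": labels.values}).to_csv(
        path, sep="\t", index=False
    )
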