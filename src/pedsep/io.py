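"""CSV readers/writers binding the pipeline stages.

All tabular artifacts are plain UTF-8 CSV ("." decimal, empty cell =
missing); the phenotype model file is JSON with a schema version.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: Columns a patient-day table must carry (beyond these, unknown columns are
#: preserved as passthrough).
REQUIRED_DAY_COLUMNS = ("patient_id", "day")


class FormatError(ValueError):
    """A malformed input file; the message names the offending row/column."""


def read_patient_days(path: str | Path) -> pd.DataFrame:
    """Read a long patient-day CSV into a typed table.

    Duplicate (patient_id, day, first_6h) rows are an error; empty cells
    become missing values; unknown columns pass through untouched.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    for col in REQUIRED_DAY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "first_6h" not in df.columns:
        df["first_6h"] = False
    df["first_6h"] = df["first_6h"].fillna(False).astype(bool)
    try:
        df["day"] = df["day"].astype(int)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: column 'day' is not integer") from exc
    dup = df.duplicated(subset=["patient_id", "day", "first_6h"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate record for patient {row['patient_id']!r} "
            f"day {row['day']}")
    return df


def write_patient_days(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_patients(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "patient_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'patient_id'")
    if df["patient_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate patient_id")
    return df


def write_labels(labels: pd.DataFrame, path: str | Path) -> None:
    labels.to_csv(path, index=False)
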