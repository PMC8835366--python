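"""Child-level record schema and delimited-text I/O.

A dataset is a pandas DataFrame with one row per child and the columns of
``RECORD_COLUMNS``: an area index, three binary illness indicators (acute
respiratory infection, diarrhoea, stunting), and the survey covariates.
``ChildRecord`` is the corresponding single-row dataclass for scalar APIs.

Files are plain comma-delimited UTF-8 text with a header row; categories
are stored as their string labels, so files diff cleanly and round-trip
losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

DISEASES = ("ari", "diarrhoea", "stunting")

CATEGORIES = {
    "residence": ("rural", "urban"),
    "education": ("none", "primary", "secondary_plus"),
    "wealth": ("poorest", "poorer_middle", "richer_richest"),
    "sex": ("male", "female"),
    "age_band": ("lt12", "m12_23", "m24_59"),
}

YEARS = (2008, 2013, 2018)

RECORD_COLUMNS = (
    "area",
    "ari",
    "diarrhoea",
    "stunting",
    "residence",
    "education",
    "wealth",
    "sex",
    "age_band",
    "mother_age",
    "year",
)


@dataclass(frozen=True)
class ChildRecord:
    """One child's outcomes and covariates."""

    area: int
    ari: int
    diarrhoea: int
    stunting: int
    residence: str
    education: str
    wealth: str
    sex: str
    age_band: str
    mother_age: float
    year: int

    def __post_init__(self) -> None:
        for d in DISEASES:
            if getattr(self, d) not in (0, 1):
                raise ValueError(f"{d} must be 0 or 1")
        for col, levels in CATEGORIES.items():
            if getattr(self, col) not in levels:
                raise ValueError(f"unknown {col} category {getattr(self, col)!r}")
        if self.year not in YEARS:
            raise ValueError(f"unknown survey year {self.year}")
        if self.area < 0:
            raise ValueError("area index must be non-negative")


class RecordValidationError(ValueError):
    """A record table violates the schema; names the offending row/column."""


def validate_records(df: pd.DataFrame, n_areas: int | None = None) -> pd.DataFrame:
    """Validate a record table against the schema, returning it unchanged.

    Raises :class:`RecordValidationError` naming the first offending cell.
    """
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise RecordValidationError(f"missing columns: {missing}")
    for col in DISEASES:
        bad = ~df[col].isin([0, 1])
        if bad.any():
            row = int(df.index[bad][0])
            raise RecordValidationError(
                f"row {row}, column {col!r}: value {df[col][bad].iloc[0]!r} not in {{0, 1}}"
            )
    for col, levels in CATEGORIES.items():
        bad = ~df[col].isin(levels)
        if bad.any():
            row = int(df.index[bad][0])
            raise RecordValidationError(
                f"row {row}, column {col!r}: unknown category {df[col][bad].iloc[0]!r}"
            )
    bad = ~df["year"].isin(YEARS)
    if bad.any():
        row = int(df.index[bad][0])
        raise RecordValidationError(
            f"row {row}, column 'year': unknown survey year {df['year'][bad].iloc[0]!r}"
        )
    if (df["area"] < 0).any():
        row = int(df.index[df["area"] < 0][0])
        raise RecordValidationError(f"row {row}, column 'area': negative area index")
    if n_areas is not None and (df["area"] >= n_areas).any():
        bad = df["area"] >= n_areas
        row = int(df.index[bad][0])
        raise RecordValidationError(
            f"row {row}, column 'area': index {int(df['area'][bad].iloc[0])} "
            f"outside 0..{n_areas - 1}"
        )
    return df


def records_to_frame(records) -> pd.DataFrame:
    """Convert an iterable of ChildRecord (or a DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    rows = [asdict(r) if isinstance(r, ChildRecord) else r for r in records]
    if not rows:
        return pd.DataFrame(columns=list(RECORD_COLUMNS))
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[ChildRecord]:
    return [ChildRecord(**row) for row in df[list(RECORD_COLUMNS)].to_dict("records")]


def write_records(records, path) -> None:
    """Write records as comma-delimited text with a header (lossless)."""
    df = records_to_frame(records)
    df = df[list(RECORD_COLUMNS)] if len(df) else df
    df.to_csv(path, index=False)


def read_records(path, n_areas: int | None = None) -> pd.DataFrame:
    """Read and validate a record file written by :func:`write_records`."""
    df = pd.read_csv(
        path,
        dtype={
            "area": np.int64,
            "ari": np.int64,
            "diarrhoea": np.int64,
            "stunting": np.int64,
            "mother_age": float,
            "year": np.int64,
        },
    )
    return validate_records(df, n_areas=n_areas)
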