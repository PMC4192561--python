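"""CSV input/output for birth registries and result tables.

Registry layout (long format, UTF-8, comma-separated, header required)::

    unit_id,latitude,population,year,month,births

with month as an integer 1-12 (January = 1).  Validation is fail-fast with
named error categories; no rows are silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .registry import BirthRecord, BirthRegistry

__all__ = [
    "RegistryIOError",
    "MissingColumnError",
    "InvalidMonthError",
    "InvalidBirthsError",
    "DuplicateRowError",
    "IncompleteRecordError",
    "EmptyResultsError",
    "read_birth_csv",
    "write_registry_csv",
    "write_results_csv",
]

REQUIRED_COLUMNS = ["unit_id", "latitude", "population", "year", "month", "births"]


class RegistryIOError(ValueError):
    """Base class for registry CSV validation failures."""


class MissingColumnError(RegistryIOError):
    pass


class InvalidMonthError(RegistryIOError):
    pass


class InvalidBirthsError(RegistryIOError):
    pass


class DuplicateRowError(RegistryIOError):
    pass


class IncompleteRecordError(RegistryIOError):
    pass


class EmptyResultsError(ValueError):
    pass


def read_birth_csv(path: str | Path) -> BirthRegistry:
    """Read and validate a long-format birth-count CSV into a registry."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnError(f"missing required columns: {missing}")
    if df.empty:
        raise IncompleteRecordError("registry file contains no rows")

    months = pd.to_numeric(df["month"], errors="coerce")
    if months.isna().any() or not np.array_equal(months, months.astype(int)):
        raise InvalidMonthError("month column must contain integers")
    if ((months < 1) | (months > 12)).any():
        bad = sorted(months[(months < 1) | (months > 12)].unique())
        raise InvalidMonthError(f"month values outside 1-12: {bad}")

    births = pd.to_numeric(df["births"], errors="coerce")
    if births.isna().any():
        raise InvalidBirthsError("births column must be numeric")
    if (births < 0).any() or not np.allclose(births, np.round(births)):
        raise InvalidBirthsError("births must be non-negative integers")

    if df.duplicated(subset=["unit_id", "year", "month"]).any():
        dup = df[df.duplicated(subset=["unit_id", "year", "month"], keep=False)]
        keys = dup[["unit_id", "year", "month"]].drop_duplicates().values.tolist()
        raise DuplicateRowError(f"duplicate (unit_id, year, month) rows: {keys[:5]}")

    records = []
    for (unit_id, year), grp in df.groupby(["unit_id", "year"], sort=True):
        if len(grp) != 12:
            raise IncompleteRecordError(
                f"record ({unit_id!r}, {year}) has {len(grp)} months, expected 12"
            )
        grp = grp.sort_values("month")
        lat = grp["latitude"].iloc[0]
        pop = grp["population"].iloc[0]
        records.append(
            BirthRecord(
                unit_id=str(unit_id),
                year=int(year),
                counts=grp["births"].to_numpy(dtype=float),
                latitude=None if pd.isna(lat) else float(lat),
                population=None if pd.isna(pop) else int(pop),
            )
        )
    return BirthRegistry(records)


def write_registry_csv(registry: BirthRegistry, path: str | Path) -> None:
    """Write a registry in the canonical long format, sorted by (unit, year, month)."""
    frame = registry.to_frame()
    frame["births"] = frame["births"].round().astype(np.int64)
    frame.to_csv(path, index=False)


def write_results_csv(
    results: pd.DataFrame, path: str | Path, sort_by: list[str] | None = None
) -> None:
    """Write a result table with deterministic row order and full float precision.

    Floats are written with 17 significant digits so a write/read round trip
    is bit-exact.
    """
    if results is None or len(results) == 0:
        raise EmptyResultsError("refusing to write an empty result table")
    frame = results
    if sort_by:
        frame = frame.sort_values(sort_by).reset_index(drop=True)
    frame.to_csv(path, index=False, float_format="%.17g")
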