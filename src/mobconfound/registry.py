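"""Core domain containers: units, birth records, registries and weighting surfaces.

A *birth record* is the atomic unit of analysis throughout the package: the
twelve monthly birth counts of one geographic unit (a country or sub-national
region) in one calendar year.  A *registry* is a collection of such records,
at most one per (unit, year).
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MONTH_DAYS",
    "SPRING_MONTHS",
    "WINTER_MONTHS",
    "month_lengths",
    "days_in_year",
    "Unit",
    "BirthRecord",
    "BirthRegistry",
    "PrevalenceSurface",
    "YobDistribution",
]

#: Month lengths of a non-leap (365-day) year, January first.
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: Zero-based indices of the spring (March-May) and winter (Nov, Dec, Jan)
#: months used by the seasonal pattern tests.
SPRING_MONTHS = (2, 3, 4)
WINTER_MONTHS = (10, 11, 0)


def month_lengths(year: int) -> np.ndarray:
    """Month lengths for ``year`` under the Gregorian leap rule (Feb=29 iff leap)."""
    lengths = MONTH_DAYS.copy()
    if calendar.isleap(year):
        lengths[1] = 29
    return lengths


def days_in_year(year: int) -> int:
    return 366 if calendar.isleap(year) else 365


@dataclass(frozen=True)
class Unit:
    """A geographic reporting unit (country or region).

    Parameters
    ----------
    unit_id
        Opaque unique label.
    latitude
        Representative latitude in degrees; drives seasonal amplitude and
        the prevalence surface.
    population
        Resident person count; enters case-sampling weights.
    """

    unit_id: str
    latitude: float
    population: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.latitude):
            raise ValueError("latitude must be finite")
        if self.population < 1:
            raise ValueError("population must be >= 1")


@dataclass(frozen=True)
class BirthRecord:
    """Monthly birth counts of one unit-year (January first).

    Counts are stored as floats because the leap-February adjustment
    (scaling February by 28/29) produces non-integral values.
    """

    unit_id: str
    year: int
    counts: np.ndarray
    latitude: float | None = None
    population: int | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (12,):
            raise ValueError("a birth record needs exactly 12 monthly counts")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("birth counts must be finite and non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


class BirthRegistry:
    """An ordered collection of :class:`BirthRecord`, one per (unit, year)."""

    def __init__(self, records: Iterable[BirthRecord]):
        self.records: list[BirthRecord] = list(records)
        index: dict[tuple[str, int], BirthRecord] = {}
        for rec in self.records:
            key = (rec.unit_id, rec.year)
            if key in index:
                raise ValueError(f"duplicate record for unit {key[0]!r}, year {key[1]}")
            index[key] = rec
        self._index = index

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BirthRecord]:
        return iter(self.records)

    def get(self, unit_id: str, year: int) -> BirthRecord:
        return self._index[(unit_id, year)]

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._index

    @property
    def unit_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.unit_id, None)
        return list(seen)

    @property
    def years(self) -> list[int]:
        return sorted({rec.year for rec in self.records})

    def records_for_unit(self, unit_id: str) -> list[BirthRecord]:
        return [rec for rec in self.records if rec.unit_id == unit_id]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (unit, year, month)."""
        rows = []
        for rec in sorted(self.records, key=lambda r: (r.unit_id, r.year)):
            for month in range(12):
                rows.append(
                    {
                        "unit_id": rec.unit_id,
                        "latitude": rec.latitude,
                        "population": rec.population,
                        "year": rec.year,
                        "month": month + 1,
                        "births": rec.counts[month],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PrevalenceSurface:
    """Per-unit disease prevalence (probability of being a prevalent case)."""

    prevalence: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.prevalence.values()), dtype=float)
        if vals.size == 0:
            raise ValueError("prevalence surface cannot be empty")
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("prevalence values must lie in [0, 1]")
        if not np.any(vals > 0):
            raise ValueError("at least one unit must have positive prevalence")

    def __getitem__(self, unit_id: str) -> float:
        return float(self.prevalence[unit_id])


@dataclass(frozen=True)
class YobDistribution:
    """Normalised year-of-birth weights for prevalent cases."""

    years: tuple = field(default_factory=tuple)
    weights: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        weights = np.asarray(self.weights, dtype=float)
        years = tuple(int(y) for y in self.years)
        if len(years) != weights.size or weights.size == 0:
            raise ValueError("years and weights must be non-empty and aligned")
        if np.any(weights < 0) or weights.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "weights", weights / weights.sum())

    def weight(self, year: int) -> float:
        try:
            return float(self.weights[self.years.index(year)])
        except ValueError:
            return 0.0
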