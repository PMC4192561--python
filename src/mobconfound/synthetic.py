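"""Synthetic birth registries with latitude- and time-structured seasonality.

Real national birth statistics show a seasonal cycle — an excess of births in
spring and a deficit in winter — whose relative amplitude grows with latitude
and has declined over recent decades.  Prevalent cases of a latitude-graded,
age-structured disease such as multiple sclerosis over-sample northern regions
and middle birth cohorts.  This module generates registries, prevalence
surfaces and year-of-birth weightings with exactly that structure so the
downstream statistics and the confounding simulation can be exercised and
calibrated without any external data.

The generative model is a single cosine harmonic on the daily birth rate:

    r(d) = (B / D) * (1 + A * cos(2*pi*(d - peak_day) / 365.25))

where ``B`` is the expected annual total, ``D`` the number of days in the
year and ``A`` the effective relative amplitude for that unit-year,

    A(lat, year) = amplitude0 * (1 + latitude_coeff*(lat - ref_latitude))
                              * decline_coeff**(year - ref_year)

clamped to [0, 0.99].  Monthly expectations are the day-sums of ``r``,
optionally perturbed by mean-one lognormal month noise, and realised counts
are Poisson.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .registry import (
    BirthRecord,
    BirthRegistry,
    PrevalenceSurface,
    Unit,
    YobDistribution,
    days_in_year,
    month_lengths,
)

__all__ = [
    "SeasonalModel",
    "simulate_birth_record",
    "simulate_registry",
    "make_prevalence_surface",
    "make_yob_distribution",
    "seasonal_month_proportions",
    "fit_seasonal_amplitude",
    "default_units",
    "default_model",
    "default_scenario",
]

PERIOD_DAYS = 365.25


@dataclass(frozen=True)
class SeasonalModel:
    """Generative parameters for structured birth rates.

    Parameters
    ----------
    baseline_annual_births
        Expected births per unit-year before noise.
    amplitude0
        Relative seasonal amplitude at the reference latitude and year.
    peak_day
        Day of year of the seasonal peak (default 105, mid-April).
    latitude_coeff
        Fractional change in amplitude per degree of latitude.
    decline_coeff
        Multiplicative amplitude decay per calendar year (1 = no decline).
    ref_latitude, ref_year
        Reference point at which the amplitude equals ``amplitude0``.
    extra_dispersion
        Sigma of mean-one lognormal multiplicative noise applied to each
        monthly mean; models record-to-record heterogeneity beyond Poisson.
    """

    baseline_annual_births: float = 60_000.0
    amplitude0: float = 0.03
    peak_day: float = 105.0
    latitude_coeff: float = 0.02
    decline_coeff: float = 0.985
    ref_latitude: float = 50.0
    ref_year: int = 1965
    extra_dispersion: float = 0.03

    def __post_init__(self) -> None:
        if self.baseline_annual_births <= 0:
            raise ValueError("baseline_annual_births must be positive")
        if not 0.0 <= self.amplitude0 < 1.0:
            raise ValueError("amplitude0 must lie in [0, 1)")
        if not 1 <= self.peak_day <= 365:
            raise ValueError("peak_day must lie in [1, 365]")
        if not 0.0 < self.decline_coeff <= 1.0:
            raise ValueError("decline_coeff must lie in (0, 1]")
        if self.extra_dispersion < 0:
            raise ValueError("extra_dispersion must be >= 0")

    def amplitude(self, latitude: float, year: int) -> float:
        """Effective relative amplitude for a unit-year, clamped to [0, 0.99]."""
        a = (
            self.amplitude0
            * (1.0 + self.latitude_coeff * (latitude - self.ref_latitude))
            * self.decline_coeff ** (year - self.ref_year)
        )
        return float(np.clip(a, 0.0, 0.99))

    def monthly_means(self, latitude: float, year: int) -> np.ndarray:
        """Expected monthly counts (noise-free) by day-summing the cosine rate."""
        amp = self.amplitude(latitude, year)
        day_sum, cos_sum = _month_cosine_sums(year, float(self.peak_day))
        return self.baseline_annual_births * (day_sum + amp * cos_sum) / days_in_year(year)


@lru_cache(maxsize=None)
def _month_cosine_sums(year: int, peak_day: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-month sums of 1 and of cos(2*pi*(d - peak_day)/365.25) over days d."""
    lengths = month_lengths(year)
    days = np.arange(1, lengths.sum() + 1, dtype=float)
    cos = np.cos(2.0 * np.pi * (days - peak_day) / PERIOD_DAYS)
    edges = np.concatenate([[0], np.cumsum(lengths)])[:-1]
    cos_sum = np.add.reduceat(cos, edges)
    cos_sum.flags.writeable = False
    return lengths.astype(float), cos_sum


def _record_seed(seed: int, unit_id: str, year: int) -> np.random.SeedSequence:
    """Stable per-record sub-seed: independent streams, reproducible registries."""
    return np.random.SeedSequence([int(seed), zlib.crc32(unit_id.encode("utf-8")), int(year)])


def simulate_birth_record(
    model: SeasonalModel, unit: Unit, year: int, seed: int | np.random.SeedSequence
) -> BirthRecord:
    """Draw one unit-year of monthly birth counts from the seasonal model."""
    if not 1 <= year <= 9999:
        raise ValueError("year outside the Gregorian range")
    rng = np.random.default_rng(seed)
    means = model.monthly_means(unit.latitude, year)
    if model.extra_dispersion > 0:
        sigma = model.extra_dispersion
        means = means * rng.lognormal(-0.5 * sigma**2, sigma, size=12)
    counts = rng.poisson(means).astype(float)
    return BirthRecord(
        unit_id=unit.unit_id,
        year=year,
        counts=counts,
        latitude=unit.latitude,
        population=unit.population,
    )


def simulate_registry(
    model: SeasonalModel, units: Sequence[Unit], years: Iterable[int], seed: int
) -> BirthRegistry:
    """One record per unit-year, each from an independent deterministic sub-seed."""
    units = list(units)
    years = [int(y) for y in years]
    if not units or not years:
        raise ValueError("units and years must be non-empty")
    ids = [u.unit_id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("unit_ids must be unique")
    records = [
        simulate_birth_record(model, unit, year, _record_seed(seed, unit.unit_id, year))
        for unit in units
        for year in years
    ]
    return BirthRegistry(records)


def make_prevalence_surface(
    units: Sequence[Unit],
    base_prev: float,
    lat_gradient: float,
    ref_latitude: float = 50.0,
) -> PrevalenceSurface:
    """Linear-in-latitude prevalence, clamped to [0, 1].

    ``prevalence(unit) = clamp(base_prev + lat_gradient * (lat - ref_latitude))``
    """
    if not 0.0 < base_prev < 1.0:
        raise ValueError("base_prev must lie in (0, 1)")
    prev = {
        u.unit_id: float(np.clip(base_prev + lat_gradient * (u.latitude - ref_latitude), 0.0, 1.0))
        for u in units
    }
    return PrevalenceSurface(prev)


def make_yob_distribution(years: Iterable[int], peak_year: int, spread: float) -> YobDistribution:
    """Gaussian-shaped year-of-birth weights, peaked at ``peak_year``.

    Emulates the age structure of prevalent cases: an excess of middle cohorts
    and fewer very young or old individuals.
    """
    years = [int(y) for y in years]
    if peak_year not in years:
        raise ValueError("peak_year must lie within the year range")
    if spread <= 0:
        raise ValueError("spread must be positive")
    yrs = np.array(years, dtype=float)
    weights = np.exp(-0.5 * ((yrs - peak_year) / spread) ** 2)
    return YobDistribution(years=tuple(years), weights=weights)


def seasonal_month_proportions(
    amplitude: float, peak_day: float = 105.0, year: int = 2001
) -> np.ndarray:
    """Closed-form monthly birth proportions of the cosine model (noise-free).

    Default year is non-leap so the proportions are on a 365-day basis; this
    is the effect-size input the power module expects.
    """
    day_sum, cos_sum = _month_cosine_sums(year, float(peak_day))
    props = day_sum + amplitude * cos_sum
    return props / props.sum()


def fit_seasonal_amplitude(mean_ratios: np.ndarray, year: int = 2001) -> tuple[float, float]:
    """Recover (amplitude, peak_day) from mean observed/expected monthly ratios.

    Least-squares fit of ``ratio - 1`` onto the month-averaged cosine and sine
    basis of the daily-rate harmonic; using month averages of the daily basis
    (rather than point values at month midpoints) avoids attenuation bias.
    """
    ratios = np.asarray(mean_ratios, dtype=float)
    if ratios.shape != (12,):
        raise ValueError("need 12 mean monthly ratios")
    lengths = month_lengths(year)
    days = np.arange(1, lengths.sum() + 1, dtype=float)
    edges = np.concatenate([[0], np.cumsum(lengths)])[:-1].astype(np.intp)
    ang = 2.0 * np.pi * days / PERIOD_DAYS
    basis = np.column_stack(
        [
            np.add.reduceat(np.cos(ang), edges) / lengths,
            np.add.reduceat(np.sin(ang), edges) / lengths,
        ]
    )
    coef, *_ = np.linalg.lstsq(basis, ratios - 1.0, rcond=None)
    amplitude = float(np.hypot(*coef))
    peak_day = float(np.arctan2(coef[1], coef[0]) / (2.0 * np.pi) * PERIOD_DAYS) % PERIOD_DAYS
    return amplitude, peak_day


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------

#: Year span of the default registry: 44 years, giving 10 x 44 = 440 records.
DEFAULT_YEARS = tuple(range(1965, 2009))


def default_units(n: int = 10) -> list[Unit]:
    """Ten region-sized units spanning southern to northern European latitudes."""
    lats = np.linspace(36.0, 70.0, n)
    return [
        Unit(unit_id=f"U{i + 1:02d}", latitude=float(lat), population=6_000_000)
        for i, lat in enumerate(lats)
    ]


def default_model() -> SeasonalModel:
    return SeasonalModel()


def default_scenario(seed: int = 0) -> dict:
    """The package's reference study: structured registry, north-weighted
    prevalence (~2x south-to-north), middle-cohort year-of-birth weights."""
    units = default_units()
    model = default_model()
    registry = simulate_registry(model, units, DEFAULT_YEARS, seed=seed)
    prevalence = make_prevalence_surface(units, base_prev=0.0015, lat_gradient=3.0e-5)
    yob = make_yob_distribution(DEFAULT_YEARS, peak_year=1975, spread=10.0)
    return {
        "model": model,
        "units": units,
        "years": DEFAULT_YEARS,
        "registry": registry,
        "prevalence": prevalence,
        "yob": yob,
    }
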