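"""Observed/expected month-of-birth statistics for birth records.

The central quantity is the ratio between the observed number of births in a
month and the number expected if the birth rate had been constant through the
year (allowing for month lengths and leap years), together with:

* a normal-approximation Poisson confidence interval on that ratio under the
  constant-rate null,
* the Pearson chi-square goodness-of-fit test of a whole record (df = 11),
* exact per-month binomial tests (the exact conditional test given the
  record's annual total),
* classification of the "typical" seasonal pattern — a nominally significant
  excess in at least one spring month (Mar-May) and/or deficit in at least
  one winter month (Nov-Jan),
* Bonferroni thresholds and registry-level significance counting.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .registry import (
    SPRING_MONTHS,
    WINTER_MONTHS,
    BirthRecord,
    BirthRegistry,
    days_in_year,
    month_lengths,
)

__all__ = [
    "MonthRatioSet",
    "GofResult",
    "SeasonPattern",
    "RegistrySummary",
    "adjust_leap_february",
    "expected_counts_constant",
    "expected_counts_reference",
    "ratio_ci_constant",
    "month_ratios",
    "gof_test",
    "binom_pvalues",
    "per_month_tests",
    "season_pattern",
    "bonferroni_threshold",
    "registry_summary",
]


def adjust_leap_february(record: BirthRecord) -> BirthRecord:
    """Scale February by 28/29 in leap years so every record spans 365 days.

    Non-leap records are returned unchanged.  The adjusted count is generally
    non-integral; downstream tests treat it as a real-valued count.
    """
    if not calendar.isleap(record.year):
        return record
    counts = record.counts.copy()
    counts[1] *= 28.0 / 29.0
    return BirthRecord(
        unit_id=record.unit_id,
        year=record.year,
        counts=counts,
        latitude=record.latitude,
        population=record.population,
    )


def expected_counts_constant(record: BirthRecord) -> np.ndarray:
    """Expected monthly counts under a constant daily birth rate.

    ``expected_i = total * days_i / days_in_year`` with that year's true
    month lengths (February 29 in leap years).
    """
    total = record.total
    if total <= 0:
        raise ValueError("record total must be positive")
    lengths = month_lengths(record.year)
    return total * lengths / days_in_year(record.year)


def expected_counts_reference(record: BirthRecord, reference: np.ndarray) -> np.ndarray:
    """Expected counts from externally supplied monthly proportions.

    Used for the country-average reference: ``reference`` is the pooled
    monthly proportion vector of the unit, and the record should be
    leap-adjusted (see :func:`adjust_leap_february`) before calling.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (12,):
        raise ValueError("reference must have 12 proportions")
    if np.any(reference < 0) or not np.isclose(reference.sum(), 1.0):
        raise ValueError("reference proportions must be non-negative and sum to 1")
    if np.any((reference == 0) & (record.counts > 0)):
        raise ValueError("zero reference proportion with positive observed count")
    total = record.total
    if total <= 0:
        raise ValueError("record total must be positive")
    return total * reference


def ratio_ci_constant(expected_monthly: float, level: float = 0.95) -> tuple[float, float]:
    """Confidence interval on the observed/expected ratio under a constant rate.

    Normal approximation to the Poisson: ``1 ± z * sqrt(E) / E``.  For a
    Norway-sized country (about 5,000 expected births per month) this gives
    (0.97, 1.03) at 95%; for a UK-sized one (about 60,000) it gives
    (0.99, 1.01).
    """
    if expected_monthly <= 0:
        raise ValueError("expected_monthly must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z / np.sqrt(expected_monthly)
    return (1.0 - half, 1.0 + half)


@dataclass(frozen=True)
class MonthRatioSet:
    """Per-month observed/expected ratios with CIs and p-values for one record."""

    unit_id: str
    year: int
    observed: np.ndarray
    expected: np.ndarray
    ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": self.unit_id,
                "year": self.year,
                "month": np.arange(1, 13),
                "observed": self.observed,
                "expected": self.expected,
                "ratio": self.ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p_month": self.p_values,
            }
        )


def month_ratios(
    record: BirthRecord, expected: np.ndarray | None = None, level: float = 0.95
) -> MonthRatioSet:
    """Observed/expected ratios with constant-rate CIs and two-sided p-values."""
    if expected is None:
        expected = expected_counts_constant(record)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(expected)
    return MonthRatioSet(
        unit_id=record.unit_id,
        year=record.year,
        observed=record.counts.copy(),
        expected=expected,
        ratios=record.counts / expected,
        ci_low=1.0 - half,
        ci_high=1.0 + half,
        p_values=per_month_tests(record, expected, sided="two"),
    )


@dataclass(frozen=True)
class GofResult:
    """Pearson chi-square goodness-of-fit result for one record (df = 11)."""

    statistic: float
    df: int
    p_value: float
    significant_bonferroni: bool | None = None

    def significant(self, alpha: float, m: int = 1) -> bool:
        return self.p_value < bonferroni_threshold(alpha, m)


def gof_test(
    record: BirthRecord,
    expected: np.ndarray,
    alpha: float | None = None,
    m: int = 1,
) -> GofResult:
    """Pearson chi-square test of a record against 12 expected counts."""
    expected = np.asarray(expected, dtype=float)
    if expected.shape != (12,):
        raise ValueError("expected must have 12 entries")
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    stat = float(np.sum((record.counts - expected) ** 2 / expected))
    df = 11
    p = float(stats.chi2.sf(stat, df))
    flag = None if alpha is None else p < bonferroni_threshold(alpha, m)
    return GofResult(statistic=stat, df=df, p_value=p, significant_bonferroni=flag)


def binom_pvalues(
    k: np.ndarray,
    n: float,
    p: np.ndarray,
    sided: str = "two",
    method: str = "exact",
) -> np.ndarray:
    """Vectorised binomial test p-values for counts ``k`` out of ``n``.

    ``sided``: "two" (doubled smaller tail, capped at 1), "greater" (excess)
    or "less" (deficit).  The exact tail is computed through the regularised
    incomplete beta function and is stable at any total; ``method="normal"``
    selects a normal approximation with continuity correction instead.
    Non-integral counts (leap-adjusted records) are rounded for the exact
    method.
    """
    p = np.asarray(p, dtype=float)
    if method == "exact":
        k = np.rint(np.asarray(k, dtype=float)).astype(np.int64)
        n_int = int(round(n))
        lower = stats.binom.cdf(k, n_int, p)
        upper = stats.binom.sf(k - 1, n_int, p)
    elif method == "normal":
        k = np.asarray(k, dtype=float)
        sd = np.sqrt(n * p * (1.0 - p))
        lower = stats.norm.cdf((k + 0.5 - n * p) / sd)
        upper = stats.norm.sf((k - 0.5 - n * p) / sd)
    else:
        raise ValueError("method must be 'exact' or 'normal'")
    if sided == "greater":
        return upper
    if sided == "less":
        return lower
    if sided == "two":
        return np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    raise ValueError("sided must be 'two', 'greater' or 'less'")


def per_month_tests(
    record: BirthRecord,
    expected: np.ndarray,
    sided: str = "two",
    method: str = "exact",
) -> np.ndarray:
    """Exact binomial test of each month's count against its expected proportion.

    Conditional on the record total, each monthly count is binomial with
    success probability ``expected_i / total``; this is the exact per-month
    test of departure from the expectation.
    """
    expected = np.asarray(expected, dtype=float)
    total = record.total
    return binom_pvalues(record.counts, total, expected / expected.sum(), sided, method)


@dataclass(frozen=True)
class SeasonPattern:
    """Which spring months show a nominal excess / winter months a deficit.

    Months are reported as calendar numbers (March=3 ... January=1).
    ``typical_pattern`` is true iff either set is non-empty — the seasonal
    signature conventionally attributed to multiple sclerosis.
    """

    spring_excess_months: tuple[int, ...]
    winter_deficit_months: tuple[int, ...]
    typical_pattern: bool


def season_pattern(
    record: BirthRecord, expected: np.ndarray, alpha_nominal: float = 0.05
) -> SeasonPattern:
    """One-sided tests: excess in Mar-May, deficit in Nov, Dec, Jan."""
    if not 0.0 <= alpha_nominal < 1.0:
        raise ValueError("alpha_nominal must lie in [0, 1)")
    p_greater = per_month_tests(record, expected, sided="greater")
    p_less = per_month_tests(record, expected, sided="less")
    spring = tuple(i + 1 for i in SPRING_MONTHS if p_greater[i] < alpha_nominal)
    winter = tuple(i + 1 for i in WINTER_MONTHS if p_less[i] < alpha_nominal)
    return SeasonPattern(
        spring_excess_months=spring,
        winter_deficit_months=winter,
        typical_pattern=bool(spring or winter),
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling the family-wise error over m tests."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    return alpha / m


@dataclass(frozen=True)
class RegistrySummary:
    """Registry-level significance counts with the per-record result table."""

    frame: pd.DataFrame
    reference_mode: str
    alpha: float
    bonferroni_alpha: float
    n_records: int
    n_significant: int
    n_significant_bonferroni: int
    n_typical_pattern: int
    n_diff_prev_year: int
    n_with_prev_year: int

    def summary(self) -> str:
        lines = [
            f"Registry summary ({self.reference_mode} reference, alpha={self.alpha:g})",
            f"  records:                          {self.n_records}",
            f"  significant GOF at alpha:         {self.n_significant}/{self.n_records}",
            f"  significant after Bonferroni      "
            f"(p < {self.bonferroni_alpha:.3g}): {self.n_significant_bonferroni}/{self.n_records}",
            f"  typical spring/winter pattern:    {self.n_typical_pattern}/{self.n_records}",
            f"  different from preceding year:    "
            f"{self.n_diff_prev_year}/{self.n_with_prev_year}",
        ]
        return "\n".join(lines)


def _country_average_reference(records: list[BirthRecord], exclude: int | None) -> np.ndarray:
    counts = np.array([r.counts for r in records])
    if exclude is not None:
        counts = np.delete(counts, exclude, axis=0)
    pooled = counts.sum(axis=0)
    return pooled / pooled.sum()


def registry_summary(
    registry: BirthRegistry,
    reference_mode: str = "constant",
    alpha: float = 0.05,
    alpha_nominal: float = 0.05,
    leave_one_out: bool = False,
) -> RegistrySummary:
    """Per-record GOF tests and significance counts across a whole registry.

    ``reference_mode="constant"`` tests each record against constant-rate
    expectations (true month lengths, February 29 included in leap years);
    ``"country_average"`` first leap-adjusts every record to a 365-day basis
    and tests against the pooled monthly proportions of the same unit
    (including the record under test unless ``leave_one_out``).  The
    preceding-year comparison is a 2x12 contingency chi-square (df = 11) on
    leap-adjusted counts.
    """
    if len(registry) == 0:
        raise ValueError("registry is empty")
    if reference_mode not in ("constant", "country_average"):
        raise ValueError("reference_mode must be 'constant' or 'country_average'")

    m = len(registry)
    bonf = bonferroni_threshold(alpha, m)
    rows = []
    adjusted_by_key = {
        (rec.unit_id, rec.year): adjust_leap_february(rec) for rec in registry
    }

    for unit_id in registry.unit_ids:
        unit_records = sorted(registry.records_for_unit(unit_id), key=lambda r: r.year)
        if reference_mode == "country_average" and len(unit_records) < 2:
            raise ValueError(
                f"country_average mode needs >= 2 records per unit (unit {unit_id!r})"
            )
        adjusted = [adjusted_by_key[(unit_id, r.year)] for r in unit_records]
        prev: BirthRecord | None = None
        for i, rec in enumerate(unit_records):
            if reference_mode == "constant":
                test_rec = rec
                expected = expected_counts_constant(rec)
            else:
                test_rec = adjusted[i]
                reference = _country_average_reference(adjusted, i if leave_one_out else None)
                expected = expected_counts_reference(test_rec, reference)
            gof = gof_test(test_rec, expected)
            pattern = season_pattern(test_rec, expected, alpha_nominal)
            if prev is not None and prev.year == rec.year - 1:
                table = np.vstack(
                    [adjusted[i].counts, adjusted_by_key[(unit_id, prev.year)].counts]
                )
                prev_p = float(stats.chi2_contingency(table, correction=False)[1])
            else:
                prev_p = np.nan
            rows.append(
                {
                    "unit_id": unit_id,
                    "year": rec.year,
                    "chi2": gof.statistic,
                    "df": gof.df,
                    "p": gof.p_value,
                    "significant": gof.p_value < alpha,
                    "significant_bonferroni": gof.p_value < bonf,
                    "typical_pattern": pattern.typical_pattern,
                    "p_prev_year": prev_p,
                }
            )
            prev = rec

    frame = pd.DataFrame(rows).sort_values(["unit_id", "year"]).reset_index(drop=True)
    with_prev = frame["p_prev_year"].notna()
    return RegistrySummary(
        frame=frame,
        reference_mode=reference_mode,
        alpha=alpha,
        bonferroni_alpha=bonf,
        n_records=m,
        n_significant=int(frame["significant"].sum()),
        n_significant_bonferroni=int(frame["significant_bonferroni"].sum()),
        n_typical_pattern=int(frame["typical_pattern"].sum()),
        n_diff_prev_year=int((frame.loc[with_prev, "p_prev_year"] < alpha).sum()),
        n_with_prev_year=int(with_prev.sum()),
    )
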