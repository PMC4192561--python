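"""Power of the chi-square goodness-of-fit test to detect birth seasonality.

As a population is split into smaller regional groups, Poisson sampling
variance in the observed/expected monthly ratios grows until it overwhelms
the systematic seasonal structure; below some annual birth count,
heterogeneity in month of birth is undetectable.  This module computes that
power curve and inverts it.

Analytic engine: standard noncentral chi-square theory for the Pearson GOF
test on a 12-cell multinomial.  With true monthly proportions ``p`` and the
constant-rate null ``p0`` (month-length proportions), the noncentrality for
``n`` annual births is

    lambda = n * sum_i (p_i - p0_i)^2 / p0_i

and the power is the upper-tail mass of chi2(df=11, lambda) beyond the
level-alpha critical value.  A simulation engine (multinomial draws through
the same Pearson statistic) cross-validates the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .registry import MONTH_DAYS

__all__ = [
    "PowerResult",
    "null_month_proportions",
    "heterogeneity_power",
    "min_detectable_birth_rate",
]

DF = 11


def null_month_proportions() -> np.ndarray:
    """Month-length proportions of a 365-day year — the constant-rate null."""
    return MONTH_DAYS / MONTH_DAYS.sum()


@dataclass(frozen=True)
class PowerResult:
    annual_births: float
    power: float
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.power <= 1.0:
            raise ValueError("power must lie in [0, 1]")


def _noncentrality(true_proportions: np.ndarray, annual_births: float) -> float:
    p0 = null_month_proportions()
    p = np.asarray(true_proportions, dtype=float)
    if p.shape != (12,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("true_proportions must be 12 non-negative values summing to 1")
    return float(annual_births * np.sum((p - p0) ** 2 / p0))


def heterogeneity_power(
    true_proportions: np.ndarray,
    annual_births: float,
    alpha: float = 0.05,
    method: str = "analytic",
    reps: int = 2_000,
    seed: int = 0,
) -> PowerResult:
    """Power of the df-11 Pearson GOF test against a seasonal alternative.

    ``method="analytic"`` uses the noncentral chi-square approximation;
    ``"simulation"`` draws ``reps`` multinomial records of size
    ``annual_births`` and reports the rejection fraction.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if annual_births <= 0:
        raise ValueError("annual_births must be positive")
    p0 = null_month_proportions()
    if method == "analytic":
        lam = _noncentrality(true_proportions, annual_births)
        crit = stats.chi2.ppf(1.0 - alpha, DF)
        power = float(stats.ncx2.sf(crit, DF, lam)) if lam > 0 else alpha
    elif method == "simulation":
        if reps < 1:
            raise ValueError("reps must be >= 1")
        rng = np.random.default_rng(seed)
        n = int(round(annual_births))
        counts = rng.multinomial(n, np.asarray(true_proportions, dtype=float), size=reps)
        expected = n * p0
        chi2 = ((counts - expected) ** 2 / expected).sum(axis=1)
        crit = stats.chi2.ppf(1.0 - alpha, DF)
        power = float((chi2 > crit).mean())
    else:
        raise ValueError("method must be 'analytic' or 'simulation'")
    return PowerResult(annual_births=float(annual_births), power=power, alpha=alpha, method=method)


def min_detectable_birth_rate(
    true_proportions: np.ndarray,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> float:
    """Smallest annual birth count at which the GOF test reaches ``target_power``.

    Bisection on the analytic power curve to a tolerance of 1 birth.
    """
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must lie in (alpha, 1)")
    if _noncentrality(true_proportions, 1.0) <= 0:
        raise ValueError("true_proportions equal the null: no finite threshold exists")

    def power_at(n: float) -> float:
        return heterogeneity_power(true_proportions, n, alpha, method="analytic").power

    lo, hi = 1.0, 2.0
    while power_at(hi) < target_power:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("failed to bracket the power target")
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi
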