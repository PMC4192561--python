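"""Monte Carlo estimation of false-positive month-of-birth associations.

The mechanism under study: cases of a latitude-graded, age-structured disease
are drawn preferentially from northern regions and middle birth cohorts —
exactly the unit-years with the strongest spring-excess/winter-deficit birth
seasonality — while the control expectation is formed by averaging national
birth statistics over *all* unit-years.  No month-of-birth effect on disease
exists anywhere in the generator, so every significant case-control
difference is a false positive by construction.  The false-positive rate of
such a mismatched design does not shrink with sample size; it grows.

Two endpoints are tracked per replicate:

* ``any_month`` — any month two-sided significant at the Bonferroni
  threshold 0.05/12;
* ``typical_pattern`` — a nominally significant (one-sided, 0.05) excess in
  at least one spring month and/or deficit in at least one winter month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mob_stats import adjust_leap_february, binom_pvalues, bonferroni_threshold
from .registry import (
    SPRING_MONTHS,
    WINTER_MONTHS,
    BirthRegistry,
    PrevalenceSurface,
    YobDistribution,
)

__all__ = [
    "CaseCollection",
    "SimConfig",
    "FprCurve",
    "pooled_control_distribution",
    "case_month_mixture",
    "sample_cases",
    "mob_association_test",
    "false_positive_curve",
    "matched_null_curve",
]


@dataclass(frozen=True)
class CaseCollection:
    """Sampled cases as (unit_id, year, month) triples; month is 1-12."""

    unit_ids: tuple[str, ...]
    years: np.ndarray
    months: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.unit_ids) == self.years.size == self.months.size):
            raise ValueError("unit_ids, years and months must be aligned")

    @property
    def n(self) -> int:
        return len(self.unit_ids)

    def month_counts(self) -> np.ndarray:
        """Aggregated case counts per birth month (length 12, January first)."""
        return np.bincount(self.months - 1, minlength=12).astype(float)


@dataclass(frozen=True)
class SimConfig:
    """Design of a false-positive-rate estimation run.

    ``n_grid`` holds the case-collection sizes N (cases per study);
    ``control_mode="expected"`` tests cases against the pooled national
    proportions directly, ``"sampled"`` draws an equally sized control arm
    and uses per-month 2x2 chi-square tests.
    """

    n_grid: tuple[int, ...] = (1_000, 5_000, 10_000, 20_000, 40_000)
    reps: int = 1_000
    alpha_bonferroni: float = bonferroni_threshold(0.05, 12)
    alpha_nominal: float = 0.05
    control_mode: str = "expected"
    n_controls: int | None = None  # sampled mode; defaults to N
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_grid or any(n < 1 for n in self.n_grid):
            raise ValueError("n_grid entries must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.control_mode not in ("expected", "sampled"):
            raise ValueError("control_mode must be 'expected' or 'sampled'")
        for a in (self.alpha_bonferroni, self.alpha_nominal):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha values must lie in (0, 1)")


@dataclass(frozen=True)
class FprCurve:
    """Estimated false-positive rate per case-collection size, per endpoint."""

    n_grid: tuple[int, ...]
    rate_any_month: np.ndarray
    se_any_month: np.ndarray
    rate_typical_pattern: np.ndarray
    se_typical_pattern: np.ndarray
    reps: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, n in enumerate(self.n_grid):
            rows.append(
                {"N": n, "endpoint": "any_month",
                 "rate": self.rate_any_month[i], "mc_se": self.se_any_month[i],
                 "reps": self.reps}
            )
            rows.append(
                {"N": n, "endpoint": "typical_pattern",
                 "rate": self.rate_typical_pattern[i], "mc_se": self.se_typical_pattern[i],
                 "reps": self.reps}
            )
        return pd.DataFrame(rows)


def _adjusted_registry_arrays(
    registry: BirthRegistry,
) -> tuple[list[tuple[str, int]], np.ndarray]:
    """Leap-adjusted (365-day basis) count matrix aligned with (unit, year) keys."""
    if len(registry) == 0:
        raise ValueError("registry is empty")
    keys = [(rec.unit_id, rec.year) for rec in registry]
    counts = np.array([adjust_leap_february(rec).counts for rec in registry])
    return keys, counts


def pooled_control_distribution(registry: BirthRegistry) -> np.ndarray:
    """Monthly proportions from summing leap-adjusted counts over all unit-years.

    This is the "averaged national statistics" control expectation.
    """
    _, counts = _adjusted_registry_arrays(registry)
    pooled = counts.sum(axis=0)
    return pooled / pooled.sum()


def _case_weights(
    registry: BirthRegistry,
    prevalence: PrevalenceSurface | None,
    yob: YobDistribution | None,
) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    """Per-(unit, year) case sampling weights and month proportions.

    ``prevalence``/``yob`` of None selects matched weighting: (unit, year)
    probability proportional to the realised record total, i.e. cases drawn
    exactly like the pooled control population.
    """
    keys, counts = _adjusted_registry_arrays(registry)
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("every record needs a positive birth total")
    month_props = counts / totals[:, None]
    if prevalence is None and yob is None:
        weights = totals.copy()
    else:
        weights = np.empty(len(keys))
        for i, (unit_id, year) in enumerate(keys):
            rec = registry.get(unit_id, year)
            pop = rec.population if rec.population is not None else 1.0
            w_unit = pop * (prevalence[unit_id] if prevalence is not None else 1.0)
            w_year = yob.weight(year) if yob is not None else 1.0
            weights[i] = w_unit * w_year
    if weights.sum() <= 0:
        raise ValueError("case sampling weights sum to zero")
    return keys, weights / weights.sum(), month_props


def case_month_mixture(
    registry: BirthRegistry,
    prevalence: PrevalenceSurface | None = None,
    yob: YobDistribution | None = None,
) -> np.ndarray:
    """Marginal birth-month distribution of a sampled case (length 12).

    The exact mixture sum over (unit, year) weights; with matched weighting
    (both arguments None) this equals :func:`pooled_control_distribution`.
    """
    _, weights, month_props = _case_weights(registry, prevalence, yob)
    return weights @ month_props


def sample_cases(
    registry: BirthRegistry,
    prevalence: PrevalenceSurface,
    yob: YobDistribution,
    n: int,
    seed: int | np.random.SeedSequence,
) -> CaseCollection:
    """Draw ``n`` independent cases weighted by prevalence and year of birth.

    Each case picks a unit with probability proportional to
    population x prevalence, a year proportional to the year-of-birth weight,
    and then a birth month proportional to that record's (leap-adjusted)
    monthly counts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for year in yob.years:
        if yob.weight(year) > 0:
            for unit_id in registry.unit_ids:
                if (unit_id, year) not in registry:
                    raise ValueError(f"registry has no record for ({unit_id!r}, {year})")
    keys, weights, month_props = _case_weights(registry, prevalence, yob)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(keys), size=n, p=weights)
    # vectorised conditional month draw via inverse-CDF on per-record proportions
    cdf = np.cumsum(month_props, axis=1)
    u = rng.random(n)
    months = np.minimum((u[:, None] > cdf[idx]).sum(axis=1) + 1, 12)
    return CaseCollection(
        unit_ids=tuple(keys[i][0] for i in idx),
        years=np.array([keys[i][1] for i in idx]),
        months=months.astype(np.int64),
    )


def _endpoint_hits(
    case_counts: np.ndarray,
    n_cases: int,
    control_dist: np.ndarray,
    control_mode: str,
    n_controls: int,
    alpha_bonferroni: float,
    alpha_nominal: float,
    rng: np.random.Generator | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised endpoint evaluation for a (reps, 12) block of case counts."""
    if control_mode == "expected":
        p_two = binom_pvalues(case_counts, n_cases, control_dist, sided="two")
        p_greater = binom_pvalues(case_counts, n_cases, control_dist, sided="greater")
        p_less = binom_pvalues(case_counts, n_cases, control_dist, sided="less")
    else:
        control_counts = rng.multinomial(n_controls, control_dist, size=case_counts.shape[0])
        p_two, z = _two_by_two_month_tests(case_counts, n_cases, control_counts, n_controls)
        p_greater = stats.norm.sf(z)
        p_less = stats.norm.cdf(z)
    any_hit = (p_two < alpha_bonferroni).any(axis=1)
    spring = list(SPRING_MONTHS)
    winter = list(WINTER_MONTHS)
    typical_hit = (p_greater[:, spring] < alpha_nominal).any(axis=1) | (
        p_less[:, winter] < alpha_nominal
    ).any(axis=1)
    return any_hit, typical_hit, p_two


def _two_by_two_month_tests(
    case_counts: np.ndarray, n_cases: int, control_counts: np.ndarray, n_controls: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-month 2x2 chi-square (month vs rest, case vs control), vectorised.

    Returns the two-sided p-values and the signed normal deviate (positive
    when the case proportion exceeds the control proportion), whose tails
    give the one-sided tests.
    """
    p1 = case_counts / n_cases
    p2 = control_counts / n_controls
    pooled = (case_counts + control_counts) / (n_cases + n_controls)
    var = pooled * (1.0 - pooled) * (1.0 / n_cases + 1.0 / n_controls)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (p1 - p2) / np.sqrt(var), 0.0)
    p_two = stats.chi2.sf(z**2, 1)  # z^2 is the 2x2 Pearson chi-square statistic
    return p_two, z


def mob_association_test(
    cases: CaseCollection | np.ndarray,
    control_dist: np.ndarray,
    control_mode: str = "expected",
    n_controls: int | None = None,
    alpha_bonferroni: float = bonferroni_threshold(0.05, 12),
    alpha_nominal: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[bool, bool, np.ndarray]:
    """Test one case collection against the control distribution.

    Returns ``(any_month_hit, typical_pattern_hit, per_month_p)`` where the
    per-month p-values are two-sided.
    """
    if isinstance(cases, CaseCollection):
        counts = cases.month_counts()
        n_cases = cases.n
    else:
        counts = np.asarray(cases, dtype=float)
        n_cases = int(round(counts.sum()))
    control_dist = np.asarray(control_dist, dtype=float)
    rng = None
    if control_mode == "sampled":
        n_controls = n_cases if n_controls is None else int(n_controls)
        if n_controls < 1:
            raise ValueError("sampled mode needs n_controls >= 1")
        rng = np.random.default_rng(seed)
    any_hit, typical_hit, p_two = _endpoint_hits(
        counts[None, :], n_cases, control_dist, control_mode,
        n_controls or 0, alpha_bonferroni, alpha_nominal, rng,
    )
    return bool(any_hit[0]), bool(typical_hit[0]), p_two[0]


def _estimate_curve(
    registry: BirthRegistry,
    prevalence: PrevalenceSurface | None,
    yob: YobDistribution | None,
    config: SimConfig,
) -> FprCurve:
    q_case = case_month_mixture(registry, prevalence, yob)
    q_control = pooled_control_distribution(registry)
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.n_grid))
    rate_any, se_any, rate_typ, se_typ = [], [], [], []
    for n, child in zip(config.n_grid, children):
        rng = np.random.default_rng(child)
        # aggregated iid case draws are exactly multinomial in the mixture
        case_counts = rng.multinomial(n, q_case, size=config.reps).astype(float)
        n_controls = config.n_controls if config.n_controls is not None else n
        any_hit, typical_hit, _ = _endpoint_hits(
            case_counts, n, q_control, config.control_mode, n_controls,
            config.alpha_bonferroni, config.alpha_nominal, rng,
        )
        for hits, rates, ses in (
            (any_hit, rate_any, se_any),
            (typical_hit, rate_typ, se_typ),
        ):
            p = float(hits.mean())
            rates.append(p)
            ses.append(float(np.sqrt(p * (1.0 - p) / config.reps)))
    return FprCurve(
        n_grid=tuple(config.n_grid),
        rate_any_month=np.array(rate_any),
        se_any_month=np.array(se_any),
        rate_typical_pattern=np.array(rate_typ),
        se_typical_pattern=np.array(se_typ),
        reps=config.reps,
    )


def false_positive_curve(
    registry: BirthRegistry,
    prevalence: PrevalenceSurface,
    yob: YobDistribution,
    config: SimConfig,
) -> FprCurve:
    """False-positive rate vs N for the mismatched (confounded) design."""
    return _estimate_curve(registry, prevalence, yob, config)


def matched_null_curve(registry: BirthRegistry, config: SimConfig) -> FprCurve:
    """Calibration control: cases perfectly matched to the pooled controls.

    (unit, year) sampling probabilities proportional to realised record
    totals make the case birth-month distribution identical to the pooled
    control distribution, so endpoint rates stay at their nominal levels at
    every N.
    """
    return _estimate_curve(registry, None, None, config)
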