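"""Ratio statistics, exact tests and registry-level counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mobconfound import (
    BirthRecord,
    BirthRegistry,
    Unit,
    adjust_leap_february,
    bonferroni_threshold,
    expected_counts_constant,
    expected_counts_reference,
    gof_test,
    month_lengths,
    month_ratios,
    per_month_tests,
    ratio_ci_constant,
    registry_summary,
    season_pattern,
    simulate_registry,
)
from mobconfound.mob_stats import binom_pvalues
from mobconfound.synthetic import SeasonalModel


def record(counts, year=2001, unit="A"):
    return BirthRecord(unit_id=unit, year=year, counts=np.asarray(counts, dtype=float))


counts_strategy = st.lists(st.integers(1, 50_000), min_size=12, max_size=12)


@pytest.mark.parametrize(
    "year, feb", [(2004, 29), (1900, 28), (2000, 29), (2001, 28), (1965, 28)]
)
def test_month_lengths_gregorian_rule(year, feb):
    lengths = month_lengths(year)
    assert lengths[1] == feb
    assert lengths.sum() == 365 + (feb == 29)
    assert list(lengths[[0, 2, 3]]) == [31, 31, 30]


class TestLeapAdjustment:
    def test_leap_february_scaled_28_29(self):
        rec = record([1000] * 12, year=2004)
        rec = BirthRecord("A", 2004, np.array([1000.0, 29_000.0] + [1000.0] * 10))
        adj = adjust_leap_february(rec)
        assert adj.counts[1] == pytest.approx(28_000.0)

    def test_non_leap_identity(self):
        rec = record([1000] * 12, year=2001)
        assert adjust_leap_february(rec) is rec

    @given(counts=counts_strategy, year=st.integers(1900, 2100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_total_drops_by_feb_over_29_in_leap_years(self, counts, year):
        rec = record(counts, year=year)
        adj = adjust_leap_february(rec)
        import calendar

        drop = rec.total - adj.total
        want = counts[1] / 29.0 if calendar.isleap(year) else 0.0
        assert drop == pytest.approx(want)


class TestExpectedCounts:
    def test_constant_rate_january(self):
        rec = record([365_000 / 12.0] * 12, year=2001)
        assert expected_counts_constant(rec)[0] == pytest.approx(31_000.0)

    def test_counts_proportional_to_month_lengths_give_unit_ratios(self):
        lengths = month_lengths(2001)
        rec = record(lengths * 100.0, year=2001)
        ratios = rec.counts / expected_counts_constant(rec)
        assert np.allclose(ratios, 1.0)

    @given(counts=counts_strategy, year=st.integers(1900, 2100))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation_both_modes(self, counts, year):
        rec = record(counts, year=year)
        assert expected_counts_constant(rec).sum() == pytest.approx(rec.total, rel=1e-9)
        ref = np.full(12, 1.0 / 12)
        assert expected_counts_reference(rec, ref).sum() == pytest.approx(
            rec.total, rel=1e-9
        )

    def test_month_length_reference_matches_constant_mode(self):
        rec = record([5000] * 12, year=2001)
        lengths = month_lengths(2001)
        ref = lengths / lengths.sum()
        assert np.allclose(
            expected_counts_reference(rec, ref), expected_counts_constant(rec)
        )

    def test_zero_reference_with_positive_observed_rejected(self):
        rec = record([10] * 12)
        ref = np.full(12, 1.0 / 11)
        ref[3] = 0.0
        ref /= ref.sum()
        with pytest.raises(ValueError):
            expected_counts_reference(rec, ref)

    def test_pooled_reference_gof_uniform_under_shared_structure(self):
        # records sharing one seasonal structure, tested against their own
        # pooled proportions: p-values should be uniform
        model = SeasonalModel(
            amplitude0=0.03, latitude_coeff=0.0, decline_coeff=1.0, extra_dispersion=0.0
        )
        unit = Unit("P", 50.0, 10)
        reg = simulate_registry(model, [unit], range(1701, 2001), seed=3)
        adjusted = [adjust_leap_february(r) for r in reg]
        pooled = np.sum([r.counts for r in adjusted], axis=0)
        ref = pooled / pooled.sum()
        pvals = [gof_test(r, expected_counts_reference(r, ref)).p_value for r in adjusted]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRatioCI:
    @pytest.mark.parametrize(
        "expected_monthly, lo, hi",
        [(5_000.0, 0.97, 1.03), (60_000.0, 0.99, 1.01)],
    )
    def test_published_intervals(self, expected_monthly, lo, hi):
        low, high = ratio_ci_constant(expected_monthly, 0.95)
        assert round(low, 2) == lo and round(high, 2) == hi

    def test_interval_collapses_for_huge_expectation(self):
        low, high = ratio_ci_constant(1e12, 0.95)
        assert low == pytest.approx(1.0, abs=1e-5)
        assert high == pytest.approx(1.0, abs=1e-5)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            ratio_ci_constant(100.0, 1.5)

    def test_expected_weighted_mean_ratio_is_one(self):
        rec = record([3100, 2500, 3300, 2800, 3000, 3000, 3100, 3200, 2900, 3100, 2950, 3050])
        mrs = month_ratios(rec)
        assert np.average(mrs.ratios, weights=mrs.expected) == pytest.approx(1.0)


class TestGof:
    def test_toy_record_statistic_eight(self, toy_record_counts):
        res = gof_test(record(toy_record_counts), np.full(12, 100.0))
        assert res.statistic == pytest.approx(8.0)
        assert res.df == 11
        # independent table value for chi-square df=11 upper tail at 8.0
        assert res.p_value == pytest.approx(0.7133, abs=5e-4)

    def test_exact_match_gives_zero_statistic(self):
        expected = np.full(12, 100.0)
        res = gof_test(record(expected), expected)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_equals_bruteforce_pearson(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            obs = rng.integers(1, 2000, size=12).astype(float)
            exp = rng.integers(1, 2000, size=12).astype(float)
            stat = 0.0  # brute-force, independent code path
            for o, e in zip(obs, exp):
                stat += (o - e) ** 2 / e
            assert gof_test(record(obs), exp).statistic == pytest.approx(stat, rel=1e-12)

    def test_null_pvalues_uniform(self, null_registry):
        pvals = [
            gof_test(rec, expected_counts_constant(rec)).p_value for rec in null_registry
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPerMonthTests:
    def test_observed_equals_expected_one_sided_at_least_half(self):
        expected = np.full(12, 100.0)
        p = per_month_tests(record(expected), expected, sided="greater")
        assert np.all(p >= 0.5)

    def test_zero_count_closed_form_deficit_tail(self):
        # 0 of 1,200 in a month with expected proportion 31/365
        p = binom_pvalues(np.array([0]), 1200, np.array([31 / 365]), sided="less")
        assert p[0] == pytest.approx((1 - 31 / 365) ** 1200, rel=1e-9)

    def test_two_sided_is_doubled_smaller_tail_capped(self):
        k = np.arange(0, 30)
        lower = stats.binom.cdf(k, 100, 0.2)
        upper = stats.binom.sf(k - 1, 100, 0.2)
        want = np.minimum(1.0, 2 * np.minimum(lower, upper))
        got = binom_pvalues(k, 100, np.full(k.size, 0.2), sided="two")
        assert np.allclose(got, want)

    def test_normal_approximation_close_to_exact_at_large_total(self):
        k = np.array([4_900, 5_100, 5_000])
        p = np.full(3, 31 / 365.0)
        exact = binom_pvalues(k, 60_000, p, sided="two", method="exact")
        approx = binom_pvalues(k, 60_000, p, sided="two", method="normal")
        assert np.allclose(exact, approx, atol=0.01)

    def test_null_one_sided_pvalues_uniform(self, null_registry):
        pvals = [
            per_month_tests(rec, expected_counts_constant(rec), sided="greater")[3]
            for rec in null_registry
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSeasonPattern:
    def test_no_departure_no_pattern(self):
        expected = np.full(12, 1000.0)
        pat = season_pattern(record(expected), expected)
        assert not pat.typical_pattern
        assert pat.spring_excess_months == () and pat.winter_deficit_months == ()

    def test_inflated_april_detected(self):
        # brute-force scan: smallest April count whose one-sided excess
        # p-value crosses 0.05
        base = np.full(12, 1000.0)
        p_apr = 1.0 / 12
        # the record total grows with the inflated April count, so the scan
        # uses the conditional n of the record actually tested
        k = 1000
        while stats.binom.sf(k - 1, 11_000 + k, p_apr) >= 0.05:
            k += 1
        counts = base.copy()
        counts[3] = k
        expected = (11_000.0 + k) * np.full(12, p_apr)
        pat = season_pattern(record(counts), expected)
        assert pat.typical_pattern and 4 in pat.spring_excess_months

    def test_alpha_zero_never_typical(self):
        counts = np.array([0.0] * 11 + [12_000.0])
        expected = np.full(12, 1000.0)
        pat = season_pattern(record(counts), expected, alpha_nominal=0.0)
        assert not pat.typical_pattern

    def test_null_typical_rate_bounded(self, null_registry):
        # union of 6 one-sided tests at 0.05: rate between the single-test
        # level and the Bonferroni upper bound 6*0.05
        hits = [
            season_pattern(rec, expected_counts_constant(rec)).typical_pattern
            for rec in null_registry
        ]
        rate = np.mean(hits)
        n = len(hits)
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n) < rate < 0.30 + 3 * np.sqrt(0.3 * 0.7 / n)


class TestBonferroni:
    def test_published_thresholds(self):
        assert bonferroni_threshold(0.05, 824) == pytest.approx(6e-5, rel=0.02)
        assert bonferroni_threshold(0.05, 12) == pytest.approx(0.0042, rel=0.01)

    def test_identity_at_m_one(self):
        assert bonferroni_threshold(0.037, 1) == 0.037

    @given(
        alpha=st.floats(1e-6, 0.99), m1=st.integers(1, 10_000), m2=st.integers(1, 10_000)
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_decreasing_in_m_linear_in_alpha(self, alpha, m1, m2):
        if m1 < m2:
            assert bonferroni_threshold(alpha, m1) > bonferroni_threshold(alpha, m2)
        assert bonferroni_threshold(alpha, m1) == pytest.approx(alpha / m1)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)


class TestRegistrySummary:
    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            registry_summary(BirthRegistry([]))

    def test_country_average_single_record_rejected(self):
        reg = BirthRegistry([record([100] * 12)])
        with pytest.raises(ValueError):
            registry_summary(reg, reference_mode="country_average")

    def test_null_registry_fraction_significant_near_alpha(self, null_registry):
        summ = registry_summary(null_registry, reference_mode="constant", alpha=0.05)
        rate = summ.n_significant / summ.n_records
        se = np.sqrt(0.05 * 0.95 / summ.n_records)
        assert abs(rate - 0.05) < 3 * se

    def test_strong_seasonality_all_records_significant(self):
        # noncentrality ~ n * amp^2 / 2 ~ 1,250 at this design: power ~ 1
        model = SeasonalModel(
            baseline_annual_births=1e6,
            amplitude0=0.05,
            latitude_coeff=0.0,
            decline_coeff=1.0,
            extra_dispersion=0.0,
        )
        units = [Unit(f"S{i}", 50.0, 10) for i in range(5)]
        reg = simulate_registry(model, units, range(1991, 2001), seed=2)
        summ = registry_summary(reg)
        assert summ.n_significant == summ.n_records == 50
        assert summ.n_significant_bonferroni == 50

    def test_summary_text_mentions_counts(self, null_registry):
        summ = registry_summary(null_registry)
        text = summ.summary()
        assert str(summ.n_records) in text and "Bonferroni" in text
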