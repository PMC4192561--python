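# Methods

## Generative model for birth registries

Each unit-year record is generated from a single-harmonic daily birth rate

    r(d) = (B / D) * (1 + A * cos(2*pi*(d - peak_day) / 365.25)),

where `B` is the expected annual total (`baseline_annual_births`), `D` the
number of days in the (Gregorian) year, and `A` the effective relative
amplitude of that unit-year,

    A(lat, year) = amplitude0
                   * (1 + latitude_coeff * (lat - ref_latitude))
                   * decline_coeff ** (year - ref_year),

clamped to [0, 0.99]. Monthly expectations are exact day-sums of `r` (month
lengths 31, 28/29, 31, ...; February 29 days when the year is divisible by 4
except centuries not divisible by 400). Each monthly mean is optionally
multiplied by mean-one lognormal noise, `exp(N(-sigma^2/2, sigma^2))` with
`sigma = extra_dispersion`, and counts are Poisson. The mean-one
parameterisation preserves the expected annual total, so the full-year cosine
integral (~0) and the noise both leave `E[total] = B`.

A single cosine is the simplest form consistent with the documented
structure — spring excess, winter deficit, latitude-increasing and
time-declining amplitude. It is a modelling stand-in, not an estimate of any
country's true seasonal shape.

Per-record reproducibility uses a stable sub-seed
`SeedSequence([seed, crc32(unit_id), year])`, so registries are reproducible
across runs and records are mutually independent.

### Default study conditions

| parameter | default | rationale |
|---|---|---|
| units | 10, latitudes 36–70°, population 6M | region-sized units spanning southern/northern Europe |
| years | 1965–2008 (44) | 10 × 44 = 440 records, a registry of realistic span |
| `baseline_annual_births` | 60,000 | ~5M population at crude birth rate 12/1,000 |
| `amplitude0` | 0.03 | calibration knob; with the noise below, record ratios span roughly ±0.1 |
| `peak_day` | 105 (mid-April) | spring peak |
| `latitude_coeff` | 0.02 /degree | ~2× amplitude range over the 34-degree span |
| `decline_coeff` | 0.985 /year | ~50% amplitude decay over 44 years |
| `extra_dispersion` | 0.03 | makes nearly all records reject the constant-rate null and differ from the preceding year, as real registries do |
| prevalence | 0.0015 + 3e-5 × (lat − 50) | ~2× south-to-north gradient |
| year-of-birth weights | Gaussian, peak 1975, sd 10 y | excess of middle cohorts among prevalent cases |

The prevalence surface is linear in latitude (clamped to [0, 1]) and the
year-of-birth weighting Gaussian; both are parameterised stand-ins for
empirical surfaces, chosen for shape (monotone gradient; unimodal age
structure), not for numeric fidelity to any published dataset.

What the generator does **not** emulate: day-of-week and holiday effects,
migration, registration-vs-birth-month lags, within-unit spatial structure,
non-sinusoidal seasonal shapes, and secular trends in the annual total.
Passing tests therefore show the statistical machinery is correct and
calibrated under the modelled structure — not that any specific real registry
has these parameter values.

## Ratio statistics

- **Constant-rate expectation**: `E_i = T * d_i / D` with the year's true
  month lengths (February 29 included in leap years).
- **Country-average expectation**: records are first leap-adjusted (February
  × 28/29 in leap years, giving a common 365-day basis; counts become
  real-valued), then tested against the pooled monthly proportions of the
  same unit. The pool includes the record under test by default (a
  leave-one-out flag exists but is off), mirroring how registry-wide
  averages are formed in practice.
- **CI on the ratio**: normal approximation to the Poisson,
  `1 ± z(level)/sqrt(E)`. The CI treats `E` as known; the coverage check in
  the acceptance suite therefore draws Poisson counts at a known mean rather
  than conditioning on realised totals (conditioning makes the counts
  multinomial and shifts coverage upward by construction).
- **GOF**: Pearson chi-square, df = 11, upper tail. The preceding-year
  comparison is a 2×12 contingency chi-square (df = 11) on leap-adjusted
  counts of both years.
- **Per-month tests**: exact binomial, conditional on the record total.
  Two-sided p-values double the smaller tail and cap at 1. The exact tail is
  evaluated through the regularised incomplete beta function and is stable
  at any total, so it is the default everywhere; a normal approximation with
  continuity correction is available (`method="normal"`). Leap-adjusted
  non-integral counts are rounded to the nearest integer for the exact test
  (≤ 0.5 birth).
- **Typical pattern**: one-sided excess tests in March–May and one-sided
  deficit tests in November, December, January at a nominal level (default
  0.05); the pattern is "typical" if any of the six rejects.

## Confounding simulation

Cases are iid draws: unit with probability ∝ population × prevalence, birth
year ∝ year-of-birth weight, month ∝ that record's leap-adjusted monthly
counts. Controls are the pooled (leap-adjusted) monthly proportions over the
whole registry — the "averaged national statistics" expectation. Both arms
live on a 365-day basis; otherwise February-29 births alone would generate a
spurious February signal of the same order as the confounding effect.

Because cases are iid, their aggregated month counts are exactly
`Multinomial(N, q)` with `q` the (unit, year)-weighted mixture of record
proportions; the curve estimators draw that multinomial directly (the
per-case sampler exists and agrees in distribution, and the tests verify the
equivalence against a direct-summation oracle). Endpoints per replicate:

- **any month**: any two-sided per-month p below 0.05/12 (the per-month
  Bonferroni threshold);
- **typical pattern**: the six one-sided tests at nominal 0.05, uncorrected.

In `expected` mode the case counts are tested against the pooled proportions
one-sample; in `sampled` mode an equally sized control arm is drawn from the
pooled proportions and each month is tested by a 2×2 chi-square (month vs
rest, case vs control), with the signed normal deviate providing the
one-sided tests. `expected` is the default; the two modes answer slightly
different questions (known national expectation vs sampled controls) and
neither is privileged by the tests.

The year weights of confounded cases are the year-of-birth weights *alone*,
not multiplied by realised birth totals — that discrepancy is precisely the
mismatch mechanism. The matched control curve (`matched_null_curve`) draws
(unit, year) ∝ realised record totals, which makes the case month
distribution identical to the pooled control distribution, so its endpoint
rates stay nominal at every N; it isolates the confounding effect by
construction. No month-of-birth effect on disease exists anywhere in the
generator, so every rejection in either curve is a false positive.

Seeding: a root `SeedSequence(seed)` spawns one child per sample size N; all
replicate draws for that N come from the child's generator, so curves are
reproducible and sizes independent.

Monte Carlo standard errors are `sqrt(p(1-p)/reps)`. Default grid
N ∈ {1,000, 5,000, 10,000, 20,000, 40,000} with 1,000 replicates; the
acceptance script uses the {1,000, 10,000, 40,000} subset, which resolves
the monotone rise of the typical-pattern endpoint well inside a desktop
minute.

## Power

Pearson GOF power under an alternative multinomial `p` against the
month-length null `p0`: noncentrality `lambda = n * sum((p - p0)^2 / p0)`,
power = upper tail of `chi2(df=11, lambda)` beyond the level-alpha critical
value. At the null the power is exactly alpha. The simulation engine draws
multinomial records and applies the same Pearson statistic; the two agree
within Monte Carlo error across the tested (amplitude × n) grid, which is the
standard regime check for the noncentral approximation.

`min_detectable_birth_rate` inverts the analytic curve by bisection (tolerance
1 birth, bracket doubling from 1). Because `lambda` is linear in `n`, doubling
the per-birth noncentrality exactly halves the threshold — asserted in tests.
The alpha, target power and effect size are free parameters: the printed
threshold is a property of the chosen effect size, not an empirical estimate
for any real population.

## Numerical choices and degenerate inputs

- Expected counts must be strictly positive; a zero reference proportion with
  a positive observed count is rejected (the ratio/test is undefined).
- Zero observed months are legal everywhere.
- `alpha_nominal = 0` makes the typical pattern unattainable (degenerate but
  allowed); Bonferroni with `m = 0` is rejected.
- Ratios are displayed at 3 decimals in tables; result CSVs write floats at
  17 significant digits so a write/read round trip is bit-exact. Rounding is
  presentation-only.
- CSV validation is fail-fast with named error classes (missing column,
  invalid month, non-integer births, duplicate row, incomplete record); no
  silent row dropping.

## Problem sizes used by the test and acceptance suites

Null calibration uses a 1,000-record constant-rate registry at 60,000
births/year; CI coverage uses 12,000 Poisson month draws at mean 5,000;
false-positive curves use 1,000 replicates per N on the 440-record default
registry; power cross-validation uses 2,000 replicates per grid cell; and
amplitude recovery averages 1,000 records at 100,000 births/year. These sizes
put Monte Carlo standard errors well below the tolerances being asserted
while keeping the full suite in the tens of seconds.

## Known limitations

- The cosine harmonic cannot represent bimodal or asymmetric seasonal shapes;
  the amplitude-recovery fit is specific to that form.
- The false-positive curves depend on the chosen prevalence gradient,
  year-of-birth spread and seasonal amplitudes; the package demonstrates and
  quantifies the mechanism rather than predicting the error rate of any
  particular published study.
- `country_average` mode requires at least two records per unit and, with its
  default include-self pooling, slightly deflates each record's GOF statistic
  when a unit has few records.
- Sibling-control designs and empirical national-statistics ingestion beyond
  the long CSV layout are out of scope.
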