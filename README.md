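# mobconfound

Statistics and simulation tools for month-of-birth (MOB) association studies
in the presence of structured birth seasonality.

Month of birth has repeatedly been reported as a risk factor for diseases such
as multiple sclerosis by comparing the birth months of cases against
expectations averaged from national birth statistics. That comparison is only
valid if birth seasonality is homogeneous across regions and years — and it is
not: national registries show a spring excess and winter deficit whose
amplitude grows with latitude and has declined over recent decades. Because
prevalent cases of a latitude-graded, age-structured disease over-sample
northern regions and middle birth cohorts, mismatching cases against pooled
national controls manufactures exactly the "typical" spring/winter pattern —
and the false-positive rate *grows* with sample size rather than shrinking.

`mobconfound` is aimed at epidemiologists and biostatisticians who want to
quantify that mechanism: it generates birth registries with the documented
seasonal structure, computes the observed/expected ratio statistics used on
real registries, estimates type-I-error curves for mismatched case-control
designs by Monte Carlo, and computes the power to detect seasonality as a
function of annual birth count.

## The statistics

For a record of monthly counts $O_1,\dots,O_{12}$ with total $T$ in a year of
$D$ days, the expected count under a constant birth rate is
$E_i = T\,d_i/D$ with $d_i$ the month length (February scaled by 28/29 in
leap years when records are put on a common 365-day basis). The package
computes:

- **ratios** $R_i = O_i/E_i$ with the constant-rate CI
  $1 \pm z_{1-\alpha/2}/\sqrt{E_i}$ — about (0.97, 1.03) for a country with
  ~5,000 expected monthly births and (0.99, 1.01) for ~60,000;
- the **Pearson goodness-of-fit** test $\sum_i (O_i-E_i)^2/E_i$ with 11
  degrees of freedom, against constant-rate or country-average expectations;
- **exact per-month binomial tests** (conditional on $T$), one- or two-sided,
  and the **typical-pattern** classification: a nominally significant excess
  in at least one spring month (Mar–May) and/or deficit in at least one
  winter month (Nov–Jan);
- **Bonferroni thresholds** $\alpha/m$;
- the Monte Carlo **false-positive curve**: cases drawn with probability
  proportional to population × prevalence over units and to an age-structured
  weight over birth years, tested against the pooled registry proportions at
  the per-month Bonferroni threshold 0.05/12 ("any month" endpoint) and at
  nominal one-sided 0.05 ("typical pattern" endpoint);
- **power**: noncentral chi-square approximation with
  $\lambda = n\sum_i (p_i-p_{0i})^2/p_{0i}$, df = 11, cross-validated by
  multinomial simulation, plus bisection for the smallest annual birth count
  reaching a target power.

## Worked example

```python
import mobconfound as mc

# constant-rate CI for a country with ~5,000 expected births per month
mc.ratio_ci_constant(5_000)            # -> (0.972, 1.028), prints as 0.97-1.03

# the default study: 10 units spanning latitudes 36-70, years 1965-2008,
# cosine seasonality with latitude-graded, time-declining amplitude
s = mc.default_scenario(seed=1)
print(mc.registry_summary(s["registry"], reference_mode="constant").summary())

cfg = mc.SimConfig(n_grid=(1_000, 10_000, 40_000), reps=1_000, seed=1)
curve = mc.false_positive_curve(s["registry"], s["prevalence"], s["yob"], cfg)
print(curve.to_frame())
```

Output:

```
Registry summary (constant reference, alpha=0.05)
  records:                          440
  significant GOF at alpha:         435/440
  significant after Bonferroni      (p < 0.000114): 404/440
  typical spring/winter pattern:    420/440
  different from preceding year:    424/430

    N        endpoint  rate  mc_se  reps
 1000       any_month 0.047  0.007  1000
 1000 typical_pattern 0.248  0.014  1000
10000       any_month 0.047  0.007  1000
10000 typical_pattern 0.280  0.014  1000
40000       any_month 0.051  0.007  1000
40000 typical_pattern 0.332  0.015  1000
```

Nearly every synthetic record rejects the constant-rate null — the registry
is genuinely heterogeneous — and although no month-of-birth effect on disease
exists anywhere in the generator, the probability that a mismatched
case-control study of N cases "replicates" the typical spring/winter pattern
climbs from 25% at N = 1,000 to 33% at N = 40,000, while a fully matched
design stays at its nominal level at every N.

## Command line

```bash
mobconfound simulate-registry --config cfg.yaml --out registry.csv
mobconfound analyze-registry  --in registry.csv --mode constant --alpha 0.05 --out results/
mobconfound confound-sim      --in registry.csv --config sim.yaml --out fpr.csv
mobconfound power             --amplitude 0.03 --peak-day 105 --alpha 0.05 --target-power 0.8
```

Registries are long-format CSV (`unit_id,latitude,population,year,month,births`,
month 1–12 with January = 1). Every run logs the package version, resolved
configuration and root seed; re-running reproduces outputs exactly.

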