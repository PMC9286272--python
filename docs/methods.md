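# Methods

## The estimand and the estimator

A reference interval (RI) for an analyte is the central 95% of its
distribution in a healthy reference population, i.e. the 2.5th and 97.5th
percentiles, each reported with a 90% confidence interval. `hemri`
estimates these nonparametrically per partition (pregnancy trimesters
T1/T2/T3, non-pregnant NP, and the pooled pregnant cohort), which makes no
distributional assumption beyond continuity — appropriate because most CBC
analytes are visibly skewed — at the price of needing ≥ 120 subjects per
partition for the limits and ~90+ for the rank-based CIs to exist.

**Limits.** In a sorted vector of n retained values the lower limit sits at
fractional rank `0.025 (n + 1)` and the upper at `0.975 (n + 1)` (Weibull
plotting positions), clamped into [1, n]. Fractional ranks are resolved by
linear interpolation between the two adjacent order statistics; this is
the natural companion of the (n + 1) plotting position. Rounding to the
nearest integer rank is available (`rank_mode="round"`) because published
studies do not always interpolate; the two differ by at most one
inter-order-statistic gap.

**Confidence intervals.** The default CI for the p-th percentile is the
distribution-free order-statistic interval: the narrowest pair
(x_(l), x_(u)) such that P(l ≤ K < u) ≥ 0.90 with K ~ Binomial(n, p)
counting observations below the true percentile; width ties are broken
toward symmetric tail probabilities. Coverage is exact (≥ nominal) for
continuous data; for n = 120 and p = 0.025 the pair is (1, 7) with
attained coverage 0.920. Because the binomial is discrete, no valid pair
exists below roughly n = 91 at 90% confidence for p = 0.025; the
estimator then falls back to a seeded percentile bootstrap (2,000
resamples of the rank-interpolated limit) and records `ci_method` so the
two constructions are never silently mixed. Bootstrap CIs for extreme
percentiles at small n are themselves fragile; they are a labelled
fallback, not an equivalent.

## Outlier exclusion

Gross errors (transcription slips, clots, analyzer artifacts) are screened
per analyte × partition with the Dixon/Reed one-third-range rule: sort the
data; an extreme is rejected when its gap D to the nearest *distinct*
neighbour exceeds one third of the range R. Choices made where the
procedure is under-specified:

- **Both tails** are tested on every pass, and the rule is **iterated** on
  the reduced vector until a pass removes nothing (capped at 10 passes);
  single-pass mode is a config switch. Iteration handles the masking case
  where a second outlier hides behind the first.
- **Ties:** all tied copies of a flagged extreme are removed together (the
  rule cannot distinguish them); D is the gap between distinct values.
- **Degenerate inputs:** zero range means the D/R ratio is taken as 0 and
  nothing is removed. The comparison is strict (`D/R > 1/3`) with a 1e-9
  relative guard so a ratio that is exactly one third is never flagged
  through floating-point noise.
- **Small samples:** below `min_n = 20` the rule degenerates (it would
  flag an extreme of {1, 2, 3}), so short vectors pass through unchanged
  with a warning marker. Reference cohorts are far larger.

The rule is location- and scale-free, hence invariant under affine
transforms. Screening independently per analyte × partition means the
retained n varies across analytes, as it should.

## Partition comparisons

Mann–Whitney U compares pregnant (pooled) vs NP and each trimester pair;
Kruskal–Wallis (tie-corrected, χ² with k−1 df) compares the three
trimesters jointly. The U test is exact (full enumeration) when the pooled
sample is ≤ 14 and tie-free, otherwise a normal approximation with
tie-corrected variance and continuity correction. The continuity-corrected
asymptotic p agrees with the exact p to < 0.01 on average at n = (7, 7);
the worst case is ~0.012, at the centre of the null distribution where the
exact test's "double the one-sided p" convention bites. Decisions are
two-sided at α = 0.05 and the pairwise trimester tests are *not*
multiplicity-adjusted, matching common practice in RI studies; a
Bonferroni option exists, off by default.

Normality is assessed descriptively with Kolmogorov–Smirnov against a
normal whose mean/SD are estimated from the same data; the asymptotic
p-value is then conservative (biased toward normality). The
Lilliefors-corrected variant is behind `corrected=True`, default off. A
zero-variance vector is reported as maximally non-normal (statistic 1).

## Out-of-range scoring

For each analyte the pregnant cohort's values are counted below/above the
manufacturer interval; values exactly at a limit are in range. The default
denominator is the full enrolled group (all pregnant subjects), the
convention under which published OOR percentages of this study design are
internally consistent; per-analyte non-missing counts are the alternative
(`denominator_mode="per-analyte"`). Conservation
(below + above = total) is enforced on all outputs.

## The synthetic cohort generator

The generator exists so every downstream stage is testable without any
data deposit. It emulates:

- **Design:** 4 partitions × 150 subjects; ~11.2% ineligible with reasons
  drawn from a categorical distribution (serology 0.40, chronic disease
  0.20, transfusion/donation 0.12, obesity 0.16, high blood pressure
  0.12). The reason list mirrors the screening rules; the weights are a
  one-time realism choice since no per-reason breakdown is published.
  Ineligible rows carry exactly the triggering field (a positive serology
  flag, BMI ≥ 30, systolic > 140, ...), so screening has a ground truth.
- **Marginals:** each analyte × partition is a three-parameter (shifted)
  lognormal solved in *closed form* from its (2.5th, 50th, 97.5th)
  percentile targets: with a = median − q_low, b = q_high − median and z
  the 97.5th standard-normal quantile, σ = ln(b/a)/z, e^μ = ab/(b−a),
  shift = median − e^μ. A symmetric triple (|b − a| ≤ 1e-9·span)
  short-circuits to Normal(median, span/2z); a left-skewed triple is
  fitted by reflection. Residuals at the anchors are ~1e-15, and a 1e-6
  tolerance check guards the degenerate near-symmetric corner. A
  two-parameter normal cannot match the asymmetric published intervals
  (e.g. WBC 4.0/8.1/13.2), which is why the family has three parameters.
- **Truncation:** analyte draws are resampled while negative (cap 100
  rounds, then clamped); for the shipped calibrations negative mass is
  negligible.
- **Contamination:** `outlier_rate` defaults to 1/150 (one sporadic gross
  outlier per analyte × partition on average), injected by displacing a
  random entry `magnitude × IQR` beyond the clean extreme of a random
  tail (default magnitude 4, jittered +0–25%; a low-side displacement
  that would go negative flips high). At these defaults an injected point
  exceeds the one-third-range threshold on the clean background by
  construction, so injected indices are a usable ground truth for the
  screen's sensitivity.

**What the generator does not model:** correlation between analytes
(Hgb–HCT coupling, differential percentages summing to 100),
gestational-week dynamics within a trimester, measurement rounding,
batch/analyzer drift, or distributional shape beyond a three-parameter
skewed family — the published tables report only quantiles, so the family
is a stand-in, not a claim about the population. Consequently, passing
tests demonstrate the *pipeline arithmetic and operating characteristics*
(coverage, sensitivity, type-I error) under a realistic marginal
structure; they do not validate the clinical intervals themselves.

## Numerical and testing notes

- Problem sizes used in the checked properties: CI coverage over 2,000
  simulated cohorts of n = 120; limit recovery on clean calibrated data
  at n = 5,000; rank-test type-I error over 500 null replicates at
  realistic group sizes; outlier operating characteristics over 100
  cohorts of n = 150. The whole suite and the acceptance script each run
  in seconds.
- At n = 5,000 the Monte-Carlo SE of a skewed analyte's 97.5th-percentile
  estimate is itself ~1–2% of the interval span, so the round-trip check
  (estimates within 2% of the calibration targets) averages four
  replicates; single replicates sit within ~2 SE.
- One published triple — RBC in the 3rd trimester, (3.76, 3.78, 4.99) —
  places the median 0.02 above the lower limit, implying an extreme skew
  (σ ≈ 2.1 on the log scale) whose upper-tail quantile has an SE near 8%
  of the span even at n = 5,000. The calibration reproduces the triple
  exactly, but round-trip recovery at that precision is not attainable
  for it and it is excluded from the representative round-trip subset.
  Similarly, the published non-pregnant PDW median (14.0) lies outside
  its own published interval (14.1–15.5); the simulator substitutes the
  published mean (14.5) as the median target (flagged in `analytes.py`).
- All randomness flows through `numpy.random.Generator` objects seeded
  from a single integer; identical seeds give byte-identical outputs
  (the manifest records seed and config hash).

## Limitations

- The blood-pressure exclusion is implemented as systolic > 140 OR
  diastolic > 90 mmHg (the conventional screening direction); both
  thresholds are configurable.
- Exclusion-reason attribution counts each subject once under the first
  firing rule in a documented order; a different order changes the
  per-reason (not the total) counts.
- No parametric or robust RI methods, no Box–Cox path, no partitioning
  statistics (partitions are defined a priori), no modelling of the
  clinical consequences of misclassification.
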