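# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices and the known limitations of `organscale`.

## Descriptive layer

Cohorts are stratified by sex × age group (early adult EA, median 16
weeks; late adult LA, median 60 weeks).  Per stratum and parameter we
report mean ± SD (sample SD, n − 1 denominator), the median, and the 95%
reference range as the 2.5th/97.5th percentiles.  Percentiles use linear
interpolation between closest ranks (the numpy default); the convention
is configurable per call because reference-range conventions differ
between labs, and the default is pinned by test.  SD is undefined (not
zero) for n = 1 and reported as missing.  Missing tibia length is a
first-class absent value: operations needing TL drop those rows and
report the drop count; nothing is imputed.  Units are fixed — HW in mg,
BW in g, TL in mm — and carried in the CSV column names; no unit
inference is attempted.

## Group tests and effect sizes

Group contrasts use Student's pooled-variance two-sample t-test
(df = n₁ + n₂ − 2, two-sided); Welch's form is available behind a flag
but is not the default because the reference analysis is the classic
Student test.  Cohen's d is (m₁ − m₂)/s_pooled with the pooled sample SD
and no small-sample correction (Hedges' g behind a flag).  The
first-listed group is group A, and the reporting convention is
female − male for sex contrasts and EA − LA for age contrasts, which
makes mouse organ/body-size contrasts come out negative (females lighter,
EA lighter).  `cohens_d_summary` computes the identical quantity from
(mean, SD, n) triples, so published summary tables can be re-analysed
without raw data; d from raw samples equals d from those samples' own
summaries exactly.

Pearson correlations are classified by |r| into negligible [0, 0.10),
weak [0.10, 0.40), moderate [0.40, 0.70), strong [0.70, 0.90) and very
strong [0.90, 1]; published threshold tables overlap at the boundaries,
so each boundary is assigned to the stronger label (0.10 → weak), a
choice pinned by test.

## Linear and allometric models

`fit_linear_model` is ordinary least squares (statsmodels under the
surface) with SEs from the residual variance on n − k − 1 df, t-based 95%
CIs, and R²/adjusted R² satisfying the exact identity
adj R² = 1 − (1 − R²)(n − 1)/(n − k − 1).  Group comparisons fit
P2 ~ P1 + group with the indicator coded 0 for Group 1 (reference) and 1
for Group 2.  Rank-deficient designs and n ≤ k + 1 are errors, not
warnings.

`fit_allometric` fits log Y = log a + b·log X by OLS using natural logs;
b is invariant to the base and to rescaling of either variable (a
transforms as a → m·a·k⁻ᵇ under x → kx, y → my, asserted to machine
precision in tests).  Isometry is tested with t = (b̂ − 1)/SE(b̂) on
n − 2 df.  Non-positive values are an error that lists the offending
rows; silently dropping them would bias b.

**Numerically exact fits.**  When data lie on a power law with no noise,
the log–log residuals are pure rounding error (R² ≥ 1 − 1e-12); the raw
slope SE is then machine noise and the Wald ratio is meaningless.  Such
fits are reported as exact: SE(b̂) = 0, and the isometry test returns
t = 0, p = 1 when b̂ is 1 to within 1e-8, otherwise ±∞ with p = 0.  The
same concern applies to t-tests on numerically constant samples (e.g.
per-subject ratios of exactly proportional data, which differ only in the
last bits): a pooled SD below 1e-12 of the data scale is treated as zero
variance and raises a degenerate-test error rather than returning a
meaningless statistic.

## Simulation cases

The two-group framework draws a body-size-like parameter P1 per subject
(Group 1: Normal(35, sd 3); Group 2: Normal(30, sd 3); n = 10 per group
by default) and builds an organ-like parameter P2 three ways:

| Case | P2 rule | structure |
|------|---------|-----------|
| 1A | 30 + 1.5·P1 + ε, ε ~ N(0, sd 3) | linear, non-proportional |
| 1B | 1.5·P1 + ε | strictly proportional |
| 1C | Normal(80, sd 5), independent | no relationship |

All Normal(m, s) parameters are mean and *standard deviation* (with
sd = 3 the n = 10 design has high power for the P1 shift, matching the
intended narrative of the cases).  The per-subject ratio defaults to
P2/P1 — organ-analog over body-analog, the orientation under which the
1A reversal and 1C leakage mechanisms operate — with `p1_over_p2`
available as a flag since the reference description is internally
inconsistent on this point.

`analyze_case` runs the three t-tests (raw P1, raw P2, ratio), fits
P2 ~ P1 + group, and flags a *reversal* when the group ordering of the
mean ratio opposes the group ordering of mean P2.  The delta method
explains the 1A reversal: E[P2/P1] ≈ 1.5 + 30·E[1/P1] ≈ 2.36 in Group 1
vs 2.51 in Group 2 even though mean P2 is higher in Group 1.
`replicate` aggregates over seeded independent replicates; degenerate
ratio tests (zero-noise proportional data) are counted exclusions, never
silent drops, and rejection rates carry the binomial Monte-Carlo SE
√(p(1 − p)/n_reps).

Exact coefficients of any single published simulated dataset are one
unseeded realization and are reproduced only in distribution; the
deterministic facts — the adjusted-R² identity, and that a shared (P1, ε)
realization pushed through the 1A and 1B rules changes *only* the fitted
intercept (by exactly 30) — are reproduced exactly.

## Synthetic cohort generator

The generator emulates the reference wildtype cohort structure: four
sex × age strata with normal marginals (EA female HW 115.9 ± 19.2 mg, BW
23.7 ± 2.6 g, TL 18.3 ± 0.6 mm, and so on) and the reported weak HW–BW
(0.21, 0.21, 0.26, −0.069) and HW–TL (0.058, 0.014, 0.055, −0.12)
correlations.  Default stratum sizes are the heart-weight availability
counts (11016, 10830, 1782, 1699; total 25,327).  Choices a user should
know:

* **Joint distribution.**  Only marginals and pairwise correlations are
  published; the trivariate-normal coupling is this package's choice.
  The TL–BW correlation is not published at all; the default 0.3 (weak)
  is an assumption.
* **Allometric mode.**  HW = a·BWᵇ·exp(ε), ε ~ Normal(0, log_noise_sd),
  encodes the power-law model explicitly for exponent-recovery and CI
  coverage testing.  With zero noise the log–log fit returns (log a, b)
  to numeric precision.
* **Positivity.**  Weights must be positive; rows with any non-positive
  draw are rejected and redrawn (capped at 100 rounds, then an error).
  With the reference parameters the closest margin is ≈ 6 SD, so the
  truncation bias is negligible.
* **Determinism.**  One generator is seeded per call and consumed in
  stratum order; identical (specs, seed) give identical tables within
  this implementation.  Cross-library bit-reproducibility is not
  promised.

What passing tests on these cohorts do **not** show: real data have
centre effects, mild non-normality, age heterogeneity within pipelines
and non-random missingness in TL — none of which the generator models.
Calibration tests show the generator hits its own targets, not that the
targets exhaust real-cohort structure.

## Ratio diagnostics

`proportionality_check` fits y ~ x and declares a ratio permissible iff
the intercept's (1 − α) CI contains 0 *and* |r| ≥ a linearity floor.
The floor defaults to 0.40, the moderate-correlation boundary: weak
correlations undermine the premise that y tracks x at all, but no
quantitative cutoff is published, so the floor is configurable and
surfaced in every report.  Origin compatibility via the CI is the
simplest faithful reading of "passes through the origin"; an equivalence
test would be a stricter extension.  `ratio_group_test` refuses by
default on an adverse verdict — operationalizing "avoid ratios unless
proportionality holds" as an API contract — and every refusal carries the
full diagnosis.

## Problem sizes

Monte-Carlo studies use 2000 replicates for rejection-rate calibration
(MC SE ≈ 0.005 at α = 0.05), 500 replicates of n = 500/group for the
reversal rate, and 500 cohorts of n = 5000 for allometric CI coverage
(MC SE ≈ 0.01); these sizes make 3-SE assertions sharp enough to detect
meaningful miscalibration while keeping the full suite fast.

## Known limitations

* No centre/hierarchical effects, robust regression, or
  multiple-testing correction (the reference analysis applies none).
* Body-surface-area normalization and dimensional indexing are out of
  scope.
* The simulation framework covers two groups only.
* One published age-contrast effect size (HW, females, EA vs LA, printed
  −0.24) is inconsistent with its own stratum summaries (which give
  ≈ −1.24, in line with the male value −1.15); it is treated as a
  suspected typographical error and excluded from verification surfaces.
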