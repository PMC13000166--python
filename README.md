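# organscale

Model-based alternatives to ratio normalization for organ-weight
phenotyping.

## The problem

Organ weights — the motivating case is heart weight (HW, mg) in laboratory
mice — are routinely "normalized" by dividing by a body-size measure such
as body weight (BW, g) or tibia length (TL, mm) before comparing groups.
The ratio HW/BW is only a valid size correction when HW is *strictly
proportional* to BW: a linear relationship whose regression line passes
through the origin, so that the ratio estimates a single constant.  In
large wildtype mouse cohorts the HW–BW and HW–TL correlations are in fact
negligible to weak (|r| ≈ 0.0–0.26 across sex × age strata), so the
proportionality assumption fails, and ratio indices can then

* **reverse** the direction of a real group difference (linear but
  non-proportional relationships, i.e. a non-zero intercept),
* **fabricate** a significant "organ" difference out of a pure body-size
  difference (independent numerator and denominator — *denominator
  leakage*).

`organscale` packages this analysis for biostatisticians and phenotyping
scientists: stratified descriptive statistics, a calibrated synthetic
cohort generator, the two-group simulation cases that expose the failure
modes, and the two model-based alternatives.

## Models

**Covariate-adjusted linear model.**  Y = α + βX + ε, fitted by OLS; group
comparisons add a 0/1 group indicator, so the group coefficient is the
organ-weight difference *at equal body size* instead of a ratio shift.

**Allometric scaling.**  Y = a·Xᵇ, fitted as log Y = log a + b·log X.
The exponent b is tested against isometry (H₀: b = 1) with
t = (b̂ − 1)/SE(b̂) on n − 2 df; b < 1 (negative allometry) means the organ
grows more slowly than the body.  Mouse heart weight scales with
b ≈ 0.38–0.40 against body weight — far from isometric.

**Effect sizes.**  Group contrasts use Student's pooled-variance t-test
with Cohen's d = (m₁ − m₂)/s_pooled, computable from raw samples or from
published summary statistics (mean, SD, n).

**Ratio guardrail.**  `ratio_group_test` refuses to compare per-subject
ratios unless a proportionality diagnosis passes: the intercept's 95% CI
must contain 0 and |r| must reach a configurable linearity floor
(default 0.40).  `force=True` overrides, returning the test together with
the adverse diagnosis.

## Worked example

```python
from organscale import (builtin_case, replicate, generate_cohort,
                        default_spec, fit_allometric, ratio_group_test,
                        stratify)
from organscale.cohort_io import AgeGroup, Sex

# Denominator leakage: P2 independent of P1, groups differ in P1 only.
rep = replicate(builtin_case("1C"), n_reps=2000, alpha=0.05, seed=7)
print(f"ratio test rejection rate (no true organ difference): "
      f"{rep.rejection_rate_ratio:.3f}")
print(f"raw P2 test rejection rate:                           "
      f"{rep.rejection_rate_p2:.3f}")

# Allometric fit on a synthetic reference cohort (EA females).
cohort = generate_cohort(default_spec(n=5000), seed=7)
ea_f = stratify(cohort)[(Sex.FEMALE, AgeGroup.EA)].df
fit = fit_allometric(ea_f["body_weight_g"], ea_f["heart_weight_mg"])
print(f"allometric exponent b = {fit.b:.3f} +/- {fit.se_b:.3f}, "
      f"isometry t = {fit.isometry_t:.2f}, p = {fit.isometry_p:.3g}")

# The guardrail refuses HW/BW comparisons on non-proportional data.
out = ratio_group_test(ea_f["heart_weight_mg"], ea_f["body_weight_g"],
                       ["A"] * 2500 + ["B"] * 2500)
print(f"HW/BW group test refused: {out.refused}")
print(f"  rationale: {out.diagnosis.rationale}")
```

Output:

```
ratio test rejection rate (no true organ difference): 0.818
raw P2 test rejection rate:                           0.053
allometric exponent b = 0.305 +/- 0.021, isometry t = -32.31, p = 3.51e-208
HW/BW group test refused: True
  rationale: regression line does not pass through the origin (intercept 81.03,
  CI [76.19, 85.86] excludes 0); |r| = 0.200 below the linearity floor 0.4 (weak)
```

The ratio test rejects a true null 82% of the time at α = 0.05 while the
raw test stays calibrated — the leakage is structural, not sampling
noise.  The fitted b ≈ 0.31 on this weakly-correlated trivariate-normal
cohort illustrates that an origin-violating relationship also reads as
strongly non-isometric; with the generator's explicit power-law coupling
the fit recovers the generating exponent (see `docs/methods.md`).

## Command line

```sh
organscale generate --out-dir out/cohort --seed 1 --n-per-stratum 2000
organscale describe --cohort out/cohort/cohort.csv --out-dir out/desc
organscale simulate --case 1C --mode replicate --n-reps 2000 --seed 1 --out-dir out/sim
organscale fit      --cohort out/cohort/cohort.csv --model allometric --x bw --out-dir out/fit
organscale diagnose --cohort out/cohort/cohort.csv --x bw --out out/diag.json
```

Every run writes its resolved parameters to `run_config.json` beside the
outputs, and every CSV carries a provenance comment line; identical
(config, seed) pairs produce byte-identical output trees.

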