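# maihda-alcohol

Intersectional MAIHDA (Multilevel Analysis of Individual Heterogeneity and
Discriminatory Accuracy) models for survey outcomes, built around the study
design used to map alcohol-consumption disparities in the US adult
population: 108 intersectional strata crossing sex (2) × race/ethnicity (6)
× age group (3) × educational attainment (3).

The package is for epidemiologists and social scientists who want to run
inter-categorical intersectional analyses on individual-level survey
records: a binary outcome (current-drinker status) and a positively skewed
continuous outcome (grams of pure alcohol per day among drinkers, modelled
on the log scale and back-transformed).

## The model

Individuals *i* are nested in intersectional strata *j*.  For a binary
outcome,

    logit Pr(y_ij = 1) = x_ij' β + u_j ,      u_j ~ N(0, σ_u²)

and for log consumption among drinkers,

    log(gpd_ij) = x_ij' β + u_j + e_ij ,      e_ij ~ N(0, σ_e²)

where *x* contains an intercept, main-effect contrasts for the four social
category axes, and survey-year dummies.  A *null* model drops the category
contrasts.  Estimation is Bayesian MCMC with diffuse priors — Normal(0, 10⁶)
on fixed effects, InverseGamma(0.001, 0.001) on variances — via conjugate
Gibbs sampling (Polya–Gamma augmentation for the logistic family).

From the null/main pair the pipeline reports:

- **VPC** = σ_u² / (σ_u² + σ_e²), the share of (latent) outcome variance
  between strata; for the logistic family σ_e² is fixed at π²/3 ≈ 3.29
  (latent-response scale).
- **PCV** = (σ_u²[null] − σ_u²[main]) / σ_u²[null], the share of
  between-stratum variance explained by additive main effects.
- **Per-stratum predictions** at a reference year: the *total* estimate
  (additive effects + the stratum's shrunken random effect) and the
  *additive-only* estimate, both on the outcome scale; their per-draw
  difference is the **interaction effect**, flagged significant when its
  95% credible interval excludes zero.  Log-scale predictions are mapped to
  mean grams/day with the log-normal retransform exp(η + σ_e²/2).

Because the stratum effects are random, small-stratum estimates shrink
toward the additive prediction in proportion to their sample size, which is
what makes estimates for sparsely populated intersections stable.

A seeded synthetic-cohort generator produces survey-like records from any
explicit generating truth (the published coefficient estimates are built in
as defaults), so every stage is testable end to end and supports
known-truth parameter-recovery experiments.

## Worked example

```python
from maihda import (CohortConfig, McmcConfig, default_design,
                    generate_cohort, run_maihda, rank_strata)

design = default_design()                       # 108 strata
cohort = generate_cohort(CohortConfig(n_individuals=54_000, design=design,
                                      year_range=(2008, 2010), seed=7))
res = run_maihda(cohort, design, "logistic",
                 McmcConfig(chains=2, iterations=1500, burn_in=500, seed=7),
                 reference_year=2009)
v = res.variance
print(f"VPC (null):  {100*v.vpc_null:.1f}%")
print(f"VPC (main):  {100*v.vpc_main:.1f}%")
print(f"PCV:         {100*v.pcv:.1f}%")
top = rank_strata(res.predictions, 3, "highest")
print(top[["rank", "label", "total", "total_lo", "total_hi",
           "additive", "interaction"]].round(1).to_string(index=False))
```

prints

```
VPC (null):  18.3%
VPC (main):  1.8%
PCV:         91.9%
 rank                   label  total  total_lo  total_hi  additive  interaction
    1   M, 21-24, White, high   93.1      91.0      94.8      89.6          3.4
    2 M, 21-24, White, medium   87.2      84.4      89.6      87.1          0.1
    3   F, 21-24, White, high   85.7      82.9      88.3      83.4          2.3
```

Read: about 18% of the variance in the propensity to drink lies between
strata; additive main effects absorb ~92% of that, leaving ~2% to
interactions.  Young White men with 4+ years of college are the likeliest
current drinkers (93.1%, 95% CI 91.0–94.8); the gap between their total and
additive-only estimates (+3.4 percentage points) is the interaction effect
for that stratum.

The same pipeline is available from the shell:

```bash
maihda simulate --seed 7 --n 54000 --out data/
maihda run --config config.yaml --out results/
```

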