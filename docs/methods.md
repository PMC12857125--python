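# Methods

## Model and procedure

The package implements two-level Bayesian random-intercept models for
inter-categorical intersectional analysis (MAIHDA).  Individuals are level
1; the level-2 units are intersectional strata — the cells of a crossed
social-category design, by default sex (Men/Women) × race/ethnicity (White,
Black, Asian, Mixed-race, AI/AN, Hispanic; all non-Hispanic except
Hispanic) × age group (21-24, 25-59, 60+) × education (high school or less
/ some college / 4+ years college), 108 strata in all.  Reference
categories are Men, White, 21-24 and high school or less; stratum
enumeration is lexicographic over axis order, so indices are deterministic.

Two outcome families are supported:

- **Binary (logistic)** for current-drinker status.  On the latent-response
  scale the individual-level variance is the constant π²/3 ≈ 3.29.
- **Linear on the log scale** for grams of pure alcohol per day (GPD) among
  drinkers.  Consumption is capped at 200 g/day before the natural-log
  transform; zero or missing consumption marks a record as out of scope for
  this family (it belongs to the binary analysis only).

For each outcome a *null* model (intercept + stratum intercepts, optional
year dummies) and a *main-effects* model (adds one contrast per
non-reference category level) are fitted.  Survey-year dummies control for
secular trends; predictions are evaluated at a single reference year
(default 2009) rather than averaged over years.

Per-stratum results at the reference year are, per posterior draw:
η_add = β₀ + x_j'β + year term, η_tot = η_add + u_j, both mapped to the
outcome scale (inverse logit × 100 for the binary family; the log-normal
mean retransform for the linear family).  The interaction effect is the
per-draw difference total − additive; intervals are 2.5/97.5 percentiles of
draws; an interaction is significant when its interval excludes zero.

## Estimation

Both families are estimated by Gibbs sampling with conjugate full
conditionals:

- **Linear**: standard Normal/InverseGamma updates using per-cell
  sufficient statistics (n, Σy, Σy²).
- **Logistic**: Polya–Gamma data augmentation.  PG(b, z) variates are drawn
  from the weighted sum-of-gammas series representation truncated at 200
  terms, with the deterministic mean of the discarded tail added back; the
  truncation bias is orders of magnitude below Monte-Carlo noise for the
  aggregated cell counts that arise here.  The sampler's first two moments
  are verified against the closed forms in the test suite.

Because every covariate is a function of the stratum and the survey year,
the likelihood is aggregated over (stratum × year) cells before sampling;
a fit on half a million records costs the same as one on a few thousand
cells.

Fixed effects and stratum intercepts are only jointly identified through
the random-effects prior, which makes a naive Gibbs scheme mix very slowly
along directions like "add δ to the intercept, subtract δ from every u_j".
After each sweep the sampler therefore performs an interweaving
(translation) step: for every stratum-level fixed-effect column the exact
Gaussian conditional of the shift δ along the likelihood-invariant
direction is sampled and applied.  This is what makes 108-strata fits mix
in a few hundred iterations; without it the stratum variance is badly
overestimated at practical chain lengths.

Priors are diffuse: Normal(0, 10⁶) per fixed effect, InverseGamma(0.001,
0.001) per variance component.  Defaults: 2 chains, 5,000 iterations with
2,500 burn-in, thin 1.  Convergence is assessed with split-chain R-hat and
bulk effective sample size (via ArviZ); a fit exceeding R-hat 1.05 or with
ESS below 200 is returned flagged (`converged=False`) with a warning, never
silently.  Identical configuration and seed give bit-identical draws;
chains use independently spawned seed streams.

A closed-form BLUP oracle (shrinkage factor λ_j = σ_u²/(σ_u² + σ_e²/n_j)
around the precision-weighted grand mean) is provided for the linear null
model and serves as an independent check on the sampler's shrunken stratum
effects (agreement r > 0.99 on balanced data in the tests).

## Variance partitioning

VPC = σ_u²/(σ_u² + σ_e²) and PCV = (σ_u²[null] − σ_u²[main])/σ_u²[null]
are evaluated per draw and averaged by default (matching computation from
unrounded posterior draws); a plug-in mode evaluating the formulas at
posterior means is available and recorded in the output.  For the PCV the
null and main draws are paired by position; the two samplers are
independent, so this is a Monte-Carlo average of the functional over
independent posterior pairs.

## Back-transformation of the skewed outcome

Predictions for consumption follow three steps per draw: form the stratum
linear predictor on the log scale; apply the log-normal mean retransform
exp(η + σ_e²/2) using that draw's residual variance; then summarise across
draws.  The retransform reduces to exp(η) as σ_e² → 0 and matches a
Monte-Carlo average of exp(N(η, σ_e²)) (tested at 10⁶ samples).  A
`retransform` hook on the prediction functions accepts a replacement —
e.g. a smearing-style estimator — without touching the rest of the
pipeline.

Point estimates are posterior means rather than medians so that the
decomposition identity total = additive + interaction holds exactly at the
summary level as well as per draw.

## Synthetic cohorts

The generator emulates the survey extract the analysis expects: four
category labels, a survey year, drinker status drawn from the two-level
logistic truth, and consumption for drinkers drawn log-normally with its
own stratum effects, capped at 200 g.  Defaults are the published
main-effects estimates (binary: intercept 1.21, women −0.55, …, stratum
variance 0.05 in the main model and 0.67 in the null; log-GPD: intercept
1.62, women −0.98, …, stratum variance 0.04/0.41, residual variance 2.98),
so a default cohort is a known-truth replica of the analysed population
structure.  Optional per-stratum interaction offsets add explicit
multiplicative effects; with offsets and stratum variance at zero the truth
is purely additive, the null condition for interaction-detection
experiments.

Choices and limits:

- Allocation is equal across strata by default, ensuring all 108 strata
  are populated; `proportional` (user weights) and `skewed` (log-normal
  weights spanning ~4 orders of magnitude, the regime where shrinkage
  matters) modes mimic realistic imbalance.
- Year effects default to zero; the survey-year machinery is exercised by
  setting nonzero values where a test needs them.
- Consumption is generated directly in grams/day; the generator does not
  emulate quantity–frequency survey items, sampling weights, household
  clustering, or within-stratum covariates beyond year.  Passing
  recovery tests therefore demonstrates correctness of the estimation
  machinery under the model's own assumptions, not robustness to
  design features of real survey data.
- Random streams are split per purpose (allocation, stratum effects,
  outcomes, missingness), so changing one rate leaves the others unchanged.

## Record filtering

Exclusion rules are small named predicates applied in declared order: a
minimum-age rule (default 21, using pre-grouping age in years; ages ≥ 85
are treated as the top-code 85), disallowed category values, missing
fields, an inclusive survey-year window (for restricted-period sensitivity
analyses), and the drinker-subset rules (non-drinkers, missing status,
unusable consumption).  The kept set is independent of rule order; each
removed record is tallied under the first matching rule.  The "inconsistent
consumption" criterion has no published definition, so the default
predicate — drinker status 1 with consumption missing or zero — is an
explicit stand-in and accepts a user-supplied replacement.

## Numerical and design notes

- Age-group bins are closed integer ranges (21-24, 25-59, 60+); ASCII
  hyphens are used in labels for CSV robustness.
- Ranking ties break by stratum index; interaction rankings consider only
  significant interactions by default (flag to include all).
- The between-outcome correlation fits consumption on drinker percentage by
  OLS; outliers are strata with |residual| > 2 × residual SD (population
  formula by default, `ddof=2` optional; the choice is recorded in the
  report object).
- Fewer than two populated strata is an error (stratum variance
  unidentified); empty strata get fully shrunken (prior) effects and still
  receive predictions.
- Estimation is unweighted throughout.

## Problem sizes used in the tests and acceptance script

Module tests run at 108 strata with tens to hundreds of individuals per
stratum and chains of a few hundred to ~1,500 iterations, sized so the full
suite completes in well under a minute while keeping Monte-Carlo error far
inside each test's tolerance.  The acceptance script uses cohorts of
100,000 individuals (the recovery targets) and 108 × 600 (the VPC target),
with 2 chains of 1,500–2,200 iterations, and averages each reported
quantity over 3–5 independent replicates: a single replicate's dominant
error is the random realisation of the 108 stratum effects
(SD ≈ √(2σ_u²/54) ≈ 0.04 on a sex contrast at σ_u² = 0.05), and averaging
replicates reduces exactly that term.

## Known limitations

- The logistic sampler's Polya–Gamma draws use a truncated series; the
  residual bias, while negligible at the default truncation, is not exactly
  zero.
- PCV pairing of independent null/main draws ignores posterior correlation
  that a joint model would capture (none exists here; the models are fitted
  separately, as is standard).
- Non-convergence is flagged, not auto-remedied; callers decide whether to
  lengthen chains.
- The CLI covers the common paths (simulate, filter, fit, maihda, report,
  run); unusual designs are expected to go through the Python API.
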