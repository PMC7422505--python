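# Methods

This note documents the models implemented in `milevel`, the defaults it
ships, the numerical choices made, and what the synthetic data generator
does and does not emulate.

## Data structure and target analysis

The package models three-level data: occasions (level 1) nested in
children (level 2) nested in schools (level 3). Each child is measured at
three paired occasions: a continuous exposure (a depressive-symptom
score) and a continuous auxiliary (a behaviour-problems score) at the
*exposure wave*, and a standardized academic z-score outcome at the
following *outcome wave*. Occasions are coded 1, 2, 3 in every model; the
cohort-style labels (exposure waves 2/4/6, outcome waves 3/5/7) survive
only as wide-column suffixes. Only the relative spacing of a linear wave
effect matters, so this coding is without loss of generality.

The target analysis is the three-level random-intercept linear mixed
model

    y_ijk = b0 + b1*exposure_ij(k-1) + b2*wave_k + b3*baseline_ij
          + b4*sex_ij + sum_a b5a*I[SES_ij=a] + b6*age_ij
          + alpha_i + alpha_ij + eps_ijk,

alpha_i ~ N(0, s3²), alpha_ij ~ N(0, s2²), eps ~ N(0, s1²). The exposure
coefficient `b1` and the three variance components are the quantities a
simulation scenario evaluates.

## Synthetic cohort generator

The generator builds a cohort sequentially: uniform age on [8, 10], sex
Bernoulli(0.5), SES quintile from equiprobable cumulative probabilities,
a baseline academic z-score from a linear regression on these, the
exposure from a three-level linear mixed model, the outcome from the
target model itself (so all truths are known), and the auxiliary from a
mixed model on the concurrent exposure and wave.

Cluster sizes come in two modes: fixed (40 schools × 30 children) and
variable, where sizes are drawn from a log-normal (median 27, sdlog 0.5)
truncated by rejection to [8, 66], rescaled by `1200/Σn`, rounded, and
the rounding deficit or excess is absorbed by the last school so that the
total is exactly 1200. Note that the rescale-and-adjust step can in
principle push an individual size slightly outside the sampling range;
the procedure (not the range) is the invariant, and the total always
holds exactly.

### Variance components from ICCs

Level-3 ICC is the correlation between observations of two children in
one school, `s3²/(s1²+s2²+s3²)`; level-2 ICC the correlation between two
occasions of one child, `(s2²+s3²)/(s1²+s2²+s3²)`. With the total fixed
at 1 an ICC pair maps to `s3² = ICC3`, `s2² = ICC2 − ICC3`,
`s1² = 1 − ICC2`; pairs with `ICC3 ≥ ICC2` are rejected (negative child
variance). The study grid crosses ICC2 ∈ {0.5, 0.2} with
ICC3 ∈ {0.15, 0.05}.

### Default parameters

The headline truth is `b1 = −0.025` (a small detrimental exposure effect
on a z-scored outcome). The remaining coefficients are modest,
cohort-plausible effects chosen once and documented here rather than
asserted as estimates from any real dataset: the exposure score has
standard deviation near 1.8 (a 0–8 scale instrument), the auxiliary near
4 (a 0–40 scale), the baseline z-score near 1, and the baseline strongly
predicts the outcome (coefficient 0.6). Exposure and auxiliary scores are
generated as unbounded continuous normals; no truncation or rounding to
the instrument ranges is applied, since every model involved is
linear-normal. All values are fields of `GeneratorParams` and can be
overridden.

## Missingness mechanisms

Only the exposure is ever masked (the outcome, auxiliary and covariates
stay complete), so a selection model on those observed quantities is MAR
by construction.

- **MCAR** masks exactly `round(p·N)` exposures per occasion by simple
  random sampling without replacement — stated proportions hold exactly
  in every dataset.
- **MAR** draws independent Bernoulli response indicators from
  `logit P(observed) = z0_k + z1·outcome_k + z2·auxiliary_k`. Default
  slopes correspond to odds ratios of about 0.6 per marginal SD of the
  outcome and 1.3 per SD of the auxiliary; the *inflated* (strong)
  variant doubles both. Per-occasion intercepts are calibrated by
  bisection on a large generated calibration sample (~34,000 children,
  ≥100,000 child-occasion draws; tolerance 0.001 on the proportion
  scale). Bisection is used rather than Newton because the Monte-Carlo
  mean response probability is monotone in the intercept and the bracket
  is cheap to verify.

The two proportion scenarios are (10, 15, 20)% and (20, 30, 40)% across
the three occasions.

## Imputation engines

All engines impute from (multivariate) normal models, include the
auxiliary at every wave among the predictors, preserve observed entries
exactly, and are reproducible given a seed.

**Joint-modelling (JM) engines.**
`jm-1l-di-wide` is classical multivariate-normal data augmentation for
`Y|X ~ MVN(XB, Σ)`: an I-step imputes each row's missing block from its
conditional normal; a P-step draws `(B, Σ)` from the complete-data
posterior with a flat prior on `B` and inverse-Wishart(dim+1, I) on `Σ`.
`jm-2l-wide` and `jm-2l-di` share a Gibbs sampler for the multivariate
random-intercept model `Y_ij = X_ij B + b_i + e_ij`, cycling
fixed-effect, random-effect and inverse-Wishart covariance draws with the
same I-step. With schools as clusters on wide data this handles the
school level by random effects; with children as clusters on long data
and school dummy indicators among the predictors, the random effects
carry the repeated-measures clustering instead. JM engines run one long
chain — burn-in 1000, one imputation saved every 100 iterations, m = 20
by default — and report split-chain potential-scale-reduction statistics
per monitored parameter, warning (not failing) above 1.10. Chains start
from complete-case moments with mean-plus-noise initialization of missing
entries.

**Chained-equations (FCS) engines.** Each incomplete variable gets a
univariate conditional model. Single-level models use the standard
Bayesian normal-regression draw (scaled inverse-chi-square variance,
conditional-normal coefficients, imputation with residual noise);
multilevel models run a short Gibbs update (10 steps per cycle by
default) of a univariate mixed model with inverse-gamma(0.001, 0.001)
variance priors, then impute from the conditional normal given drawn
parameters and intercepts. Wide-format engines regress each incomplete
wave on the same variable at all other waves plus all auxiliary, outcome
and baseline variables (and school dummy indicators for the DI variant);
long-format engines pair the exposure with the concurrent-row outcome and
auxiliary. Each imputation is an independent chain with 10 burn-in
cycles (the common chained-equations default); targets are visited in
ascending wave order, which is immaterial at Monte-Carlo resolution
because results are ordering-insensitive (tested). A Blimp-style preset —
longer within-cycle Gibbs runs — is available by raising `gibbs_steps`;
the package makes no claim to distinguish ML-based from fully Bayesian
three-level FCS implementations, whose differences were small in this
design.

Dummy-indicator engines fail fast, with the offending columns named, when
a cluster contributes no observed target values (the classic sparse-data
failure of DI parameterizations). A three-level JM engine is deliberately
absent: the comparison set is the seven engines above plus the
available-case and full-data comparators.

## Analysis: nested REML in O(N)

For nested random intercepts, each school's marginal covariance is
`V_i = a I + b blockdiag_j(J_k_ij) + c J_n_i`. The child blocks invert in
closed form and the school term is a Sherman–Morrison rank-one update, so
`X'V⁻¹X`, `X'V⁻¹y` and `log|V|` reduce to child-level sums: one REML
criterion evaluation costs O(N p²) and a cohort-size fit takes ~30 ms.
The criterion is minimized over log-variances by L-BFGS-B from two starts
(moment-flavoured and equal-split). Because finite-difference L-BFGS-B
can stall on its first line search, every solution is verified by a
central-difference gradient check and, on failure, polished by
Nelder–Mead and re-refined; fits flag non-convergence rather than fail
silently. Variances driven to the lower bound (1e-7) are returned as
exactly 0 with a boundary flag. Fixed effects and model-based SEs come
from GLS at the optimum. REML was chosen over ML as the standard
variance-component default; at the simulated scale the difference is
negligible. The fitter reproduces balanced nested-ANOVA closed forms to
1e-6 and agrees with an independent general-purpose mixed-model
implementation to the same order.

Available-case analysis drops exactly the occasion rows with a missing
exposure, keeping a child's other occasions.

## Pooling and evaluation

Exposure-coefficient estimates are pooled by Rubin's rules with
Barnard–Rubin degrees of freedom (complete-data df = rows − fixed
effects). Variance components, which carry no SE from the REML fit, are
pooled as the simple mean across imputations — a documented, configurable
choice. Available-case and full-data intervals use the normal
approximation, appropriate at 1200 children.

Performance measures follow the standard simulation-reporting
definitions: bias (mean estimate minus truth), percentage bias, empirical
SE (SD of estimates), model-based SE (arithmetic mean of reported SEs —
deliberately not the root-mean of variances), coverage of 95% intervals,
`mcse_bias = emp_se/√R` and `mcse_coverage = √(c(1−c)/R)`. At 1000
replications the coverage MCSE at the nominal level is ≈0.7 percentage
points; the package's built-in scenarios default to 200 replications
(MCSE ≈1.5 pp), a deliberate scaled-down problem size that keeps a full
scenario within minutes on one CPU while leaving the stochastic
conclusions resolvable at 3-MCSE tolerance. Replication seeds descend
from the master seed through a spawning scheme, and all methods within a
replication share one generated dataset and one missingness realization,
so method comparisons are paired. Per-method failures are logged and
counted; a replication failing for every method aborts the scenario.

## What the generator does not emulate

Passing tests demonstrate correct behaviour under the generator's
assumptions — linear-normal models at every stage, random intercepts
only, exposure-only missingness, regular wave spacing. Real cohorts
depart from these in ways the package does not simulate: bounded and
skewed questionnaire scores, missingness in outcomes and covariates and
at higher levels, random slopes, irregular visit schedules, and MNAR
mechanisms. Results here say nothing about those settings; in particular
wide-format engines are structurally unusable with irregular measurement
times, and dummy-indicator engines are known to misbehave with many
small clusters and low ICCs.

## Other known limitations

- Incomplete variables must be continuous; categorical targets would need
  latent-normal or logistic conditional models.
- The FCS engines do not implement cluster-mean augmentation, so the
  formal multilevel JM/FCS equivalence conditions are out of scope (the
  analysis model assumes no level-specific associations, making the
  distinction immaterial here).
- Rubin pooling of variance components by simple means has no interval
  attached; only point performance (bias) is evaluated for them.
- The ACA comparator uses normal intervals; with few clusters a t
  reference might be preferred.
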