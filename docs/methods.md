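# Methods

## The model and its assumptions

`ipdmed` fits a two-wave longitudinal mediation model to participant-level data
pooled across randomized trials. Two linear equations are estimated on the same
rows with the same weights: equation A regresses the post-baseline mediator on
intervention-arm dummies (control is always the omitted reference; dummies are
generated in the fixed order MI+PF, PF, GMI), the baseline outcome, the
baseline mediator, and three binary demographic covariates; equation B
regresses the post-baseline outcome on the same terms plus the post-baseline
mediator. The indirect effect of arm *k* is the product `a_k × b_med`, the
total effect is `direct_k + indirect_k`, and the identity
`total = direct + indirect` holds by construction on both the raw and the
standardized scale.

Assumptions: scores are commensurate across studies (harmonization is upstream
of this package and out of scope); both equations are linear with
homogeneous coefficients across studies (the pooled model is a fixed-effect,
"one-stage" estimate); errors of the two equations are uncorrelated, making
the system recursive; participant-level missingness is missing at random given
the observed variables; arms a study did not evaluate, and covariates constant
within a study, are missing *by design* at the study level and are excluded
from that study's sub-model rather than imputed.

Because the system is recursive with uncorrelated errors, equation-wise
weighted least squares coincides with the joint-system estimator on complete
data, so the package estimates the two equations separately instead of
invoking an SEM engine; the bootstrap supplies all interval inference. A
cluster-robust (study-clustered) sandwich standard error is available purely
as a diagnostic cross-check of the bootstrap intervals.

## Weights

Participants in study *s* receive weight `1/√n_s`, a design-based device that
keeps very large trials from dominating the pooled estimate while still letting
them contribute more than small trials. Weights are normalized to sum to the
total sample size; WLS point estimates are invariant to that scale, so
normalization affects only reported diagnostics. Within a single-study
sub-model weights are uniform — the scheme is a between-study device.

## Standardization

"Standardized with respect to the outcome" divides every mediator-equation
quantity by the weighted SD of the post-baseline mediator and every
outcome-equation quantity (direct, indirect, total, and `b_med` per unit of
the mediator) by the weighted SD of the post-baseline outcome, both computed on
the current (imputed) analysis sample and averaged across imputations when
pooling. The standardized indirect effect `indirect/sd_B` equals
`(a/sd_A) × (b_med · sd_A / sd_B)`, so the decomposition identity survives
standardization. The mediator→outcome path is exposed in both conventions —
per raw unit (`std_b_med_per_unit`) and per SD of the mediator
(`std_b_med_per_sd`) — because both readings are common in path diagrams.

## Missing data: EM imputation with bootstrapped draws

Participant-level missingness is handled by multivariate-normal multiple
imputation in the EMB (expectation-maximization with bootstrapping) style:

1. EM finds the ML mean/covariance of the incomplete matrix under MAR.
   Convergence: max absolute parameter change < 1e-6, capped at 500 iterations
   (non-convergence returns the last iterate with a flag). Initialization:
   observed means and a diagonal covariance.
2. For each of the m imputations, the rows are bootstrapped and EM is re-run on
   the resample — this is the parameter draw that propagates estimation
   uncertainty.
3. Each incomplete row of the *original* matrix is completed with a draw from
   the conditional normal of its missing block given its observed block under
   those parameters. Binary covariates are imputed continuously and rounded at
   0.5. Observed cells are never altered.

The imputation model contains both waves of mediator and outcome, the three
demographic covariates, the treatment dummies and study-membership dummies, so
imputations respect arm and study differences. Imputation is pooled across
studies (with those design dummies) rather than run per study: several strata
are far too small to support their own 12-parameter covariance, and the design
dummies give every study its own mean structure, which is the congenial
middle ground. Columns without variation in scope (e.g., sex in an all-female
study) are excluded from the imputation model; if such a column still has
missing cells they are filled with the observed constant — study-level missing
variables are never imputed.

A numerical guard: a ridge of 1e-6 is added to the diagonal of the
observed-block covariance before factorization in the E-step and in the
conditional draws. The stored M-step covariance itself is unridged, so on
complete data EM reproduces the sample moments (divisor n) exactly. Rows with
no observed cell are dropped from EM with a warning. Point estimates are
pooled across imputations by the arithmetic mean (Rubin's rule for point
estimates; within/between variances are unnecessary because interval inference
is by bootstrap).

## Bootstrap-then-impute inference and BCa intervals

Replicates resample participants with replacement *within every study × arm
stratum*, so each bootstrap dataset preserves every stratum size exactly —
this respects the clustered, stratified design. Imputation runs inside each
replicate (bootstrap first, impute second), so imputation uncertainty is
re-evaluated per replicate. Each replicate's m imputed fits are pooled by the
mean; a replicate whose imputation or fit fails numerically (a Cholesky
failure on a degenerate resample) is discarded and counted, and more than 10%
discards aborts the run.

Two point estimates are reported and labeled: the mean across bootstrap
replicates (the headline estimate) and the original-sample estimate computed
through the same imputation-and-pool path with a reserved seed stream. BCa's
bias-correction constant `z0` is anchored at the original-sample estimate
(`z0 = Φ⁻¹` of the share of replicates below it, ties counted half; an empty
tail is clamped with 1/(2B) tail mass and a warning). Acceleration uses the
jackknife skewness formula over **leave-one-study-out** estimates — leaving
out whole studies respects the clustering and costs S refits instead of N
refits through imputation; the no-acceleration (bias-corrected-only) interval
is available via `acceleration_scheme="NONE"` and is the default within
single-study sub-models, where a study-level jackknife is undefined. A
parameter that becomes inestimable when some study is left out contributes no
jackknife value and falls back to zero acceleration. Empirical quantiles use
linear interpolation between order statistics. No multiplicity adjustment is
applied; intervals are per-parameter.

Every replicate draws all randomness from `default_rng([seed, replicate])`, so
any single replicate is reproducible in isolation and parallel execution
(`n_jobs`) cannot change results.

## Synthetic data generator

The generator emulates the structure of a ten-trial pooled synthesis:
per-study arm layouts (most studies evaluate one intervention vs. control; one
evaluates all three), per-study demographic composition given as counts
(including one all-female and three all-first-year studies), study-specific
bivariate-normal baselines (correlation −0.35 between baseline mediator and
outcome by default), post-baseline scores generated from the two equations
with known coefficients, and MAR masking whose per-study, per-variable
marginal rates are hit by numerically solving the logistic intercept, with a
slope of 0.3 on the centered baseline outcome (zero for the baseline outcome's
own, tiny, missingness). Preset generating effects are deliberately small and
realistic for brief interventions: the PF→mediator path is ≈0.07 SD, the
mediator→outcome path ≈ −0.22 SD per mediator SD, hence a true standardized
indirect effect near −0.015; residual SDs of 0.68 put each equation's R² near
0.43.

Between-study heterogeneity (random intercept or treatment-slope shifts) is a
stress dial with default zero: the default conditions are exactly the ones
under which the pooled fixed-effect model is correctly specified, which is
what the estimator claims to estimate. Nonzero `tau_*` settings exist to probe
robustness, not to describe the default conditions. The generator does not
simulate item-level measurement (scores arrive already commensurate), MNAR
mechanisms, more than two waves, or informative cluster sizes — so passing
tests demonstrate correctness of the estimator and its inference under the
stated model, not robustness to measurement error or non-ignorable dropout.

Zero residual SDs are allowed as an identification check, with one caveat: a
*fully* noiseless mediator equation makes the post-baseline mediator an exact
linear combination of the outcome equation's other regressors, so each
equation must be checked in its own noiseless limit.

## Numerical choices

- Rank check (public fitting path): smallest singular value < 1e-10 × largest
  → error naming the collinear terms. The bootstrap hot path uses Cholesky
  factorization of the normal equations; its failure marks the replicate
  discarded.
- Residual variance uses the n − p divisor; R² comes from weighted sums of
  squares about the weighted mean and is reported per equation.
- EM: tol 1e-6, max 500 iterations, E-step ridge 1e-6 (see above).
- CSV contract: comma-separated UTF-8, empty string or `NA` = missing; study
  and arm may never be missing; unknown arm labels fail loudly with the row
  number.
- Participants missing an entire assessment wave are retained and imputed
  (their treatment/study columns are always observed, so every row has
  observed cells).

## Problem sizes in the shipped runs

The packaged test-and-reproduction runs scale the inference down so a complete
check runs in minutes: interval-coverage simulations use 200 generated
datasets at B = 500 replicates with m = 1 (complete data); the
reproduction script uses B = 200 replicates with m = 5 imputations on the
MAR-masked preset; examples use B = 60–100. A production analysis should use
B = 5000 and m = 10 (the defaults of `BootstrapConfig`); all quantities scale
without code changes.

## Known limitations

- Two assessment waves only; continuous treatments, non-identity links,
  latent-variable measurement models, and model-based multilevel (random
  slope) estimation are out of scope.
- The imputation engine is a single joint normal; it does not implement
  chained equations or transformations of bounded variables.
- With only ~10 studies, the jackknife acceleration estimate is itself noisy;
  the BC (no-acceleration) interval is one switch away for comparison.
- Interval coverage is demonstrated under the generator's conditions
  (homogeneous effects, MAR); under strong unmodeled between-study
  heterogeneity the within-stratum bootstrap cannot see between-study
  variance, and intervals for arms carried by few studies will undercover.
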