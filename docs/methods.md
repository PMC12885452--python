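# Methods

## Design and estimands

The package analyses stepped-wedge cluster randomized trials in long format:
every participant contributes one row per assessment wave, all clusters start
under control, and each cluster's sequence determines the week it crosses
over to the intervention.  The default geometry is 6 clusters of sizes
81/48/60/75/57/26 (347 participants), two clusters per sequence, crossovers
after 8/16/24 weeks, and 5 waves spaced 8 weeks apart, so the three
sequences have treatment vectors (0,1,1,1,1), (0,0,1,1,1) and (0,0,0,1,1).

Exposure is coded "once crossed, always treated": post-crossover waves count
as treated even after the 8-week program window has ended, because later
assessments follow program completion and no washout is assumed.  The
alternative "currently in program" coding is available via
`exposure_coding="active_program"`.

The target estimand is the product-of-coefficients indirect effect `a*b`
from two random-intercept linear mixed models (REML), fitted on waves 2–5
with the wave-1 outcome entering only as a covariate.  Modelling wave 1 as a
response while also adjusting for it would double-count the baseline, so
wave-1 rows are never analysis rows.  The covariate set is cluster, gender,
profession, age, contract type, trainee status and the baseline outcome;
cluster enters as a fixed (dummy-coded) covariate in the mediation models
and as a random intercept only in the lagged model.  Reference levels for
dummy coding are fixed (cluster 1, female, physician, non-temporary,
non-trainee) so coefficient signs are reproducible.

## Bootstrap inference

The resampling unit is the **participant trajectory**, stratified by cluster
so each resample preserves the cluster sizes.  Row-level resampling would
destroy the within-participant correlation that the random intercept models,
and is offered only as a comparison flag.  Resampled participants are
relabelled, so a trajectory drawn twice contributes two independent
random-intercept groups.  Per iteration both models are refitted and `a*b`
recorded; the 95% CI is the 2.5th/97.5th percentile of the draws (linear
interpolation between order statistics; nearest-rank available), and the
p-value is the two-sided sign-crossing proportion
`min(1, 2*min(#draws<=0, #draws>=0)/n_used)`.  Draws therefore yield p-values
in steps of `2/n_boot`; rendered output shows values below that resolution
as a "<" bound.  An iteration whose fit fails is redrawn up to 3 times with
a fresh substream and then dropped; the run aborts if fewer than 95% of the
requested iterations survive.  Every iteration seeds its generator from
`(seed, iteration, attempt)`, so results are bit-identical across runs and
worker counts.

## Mixed-model fitting

For a single random intercept the package fits exact REML by profiling:
with compound-symmetric within-group covariance the GLS problem reduces to a
one-dimensional search over the variance ratio `lambda = s_u^2/s_e^2`
(Woodbury identity per group), solved by bounded scalar minimisation over
`log lambda` in [-14, 14] with explicit evaluation of the boundary
`lambda = 0`.  At the boundary the fit reproduces ordinary least squares
exactly.  This is the same criterion general mixed-model software maximises
(agreement with an independent implementation is part of the test suite) but
runs in ~2 ms per fit, which makes 1000-iteration bootstraps and
200-replicate simulation studies practical on one CPU.  The nested
participant-within-cluster model used by the lagged analysis delegates to
`statsmodels` `MixedLM` with a participant variance component inside cluster
groups, trying the lbfgs, powell and cg optimizers in turn because boundary
fits (true cluster variance near zero) defeat the default optimizer.
Single-fit p-values and CIs for a, b and the direct effect use the Wald
normal approximation; no degrees-of-freedom correction is applied since
headline inference is bootstrap-based.  Complete-case rows are used per
model and the dropped count is recorded on the fit object.

## Synthetic-data generator

The generator emulates the measurement structure of the motivating trial:
instrument score ranges (PSS 0–40, PHQ-9 0–27, GAD-7 0–21, BSI-GSI 0–72,
CD-RISC 0–40, FFMQ facets 1–5, SOCS 20–100, AAQ-II 7–49), baseline means and
spreads per instrument, and covariate marginals (85.6% female, age
45.01 ± 11.17 truncated to 18–70, occupations 42.4/26.8/30.8%, 18.4%
temporary contracts, 9.8% trainees).  Default injected paths are a = 2.62,
b = -0.48, c' = -2.77 on the CD-RISC/PSS scales, giving a true indirect
effect of -1.2576.

Generative structure: wave-1 scores carry stable individual differences
`eta_i`; post-baseline waves inherit them **only through the observed
baseline score** (coefficients `baseline_effect_outcome = 0.5` and
`baseline_effect_mediator = -0.15`), plus an independent post-baseline
participant intercept and residual.  This matches the analysis models —
which adjust for the baseline outcome while fitting a participant random
intercept — exactly; transmitting `eta_i` directly into later waves instead
would make the baseline covariate correlate with the random effect and bias
the b-path toward zero, a well-known hazard of baseline adjustment in mixed
models that the generator deliberately avoids so that recovery tests have an
unambiguous truth.

Variance components are free parameters, not facts about the emulated trial
(which reports only baseline SDs): defaults split each instrument's baseline
variance evenly between the participant level and the residual (baseline
PSS SD 6.33 -> 4.48/4.48; CD-RISC SD 6.79 -> 4.8/4.8; secondary instruments
use their printed SDs with the same 0.5 share).  Time slopes default to 0
because the mediation models' covariate set contains no time term: in a
stepped wedge a secular trend is confounded with treatment, so a nonzero
default would make the injected paths unrecoverable by the stated analysis
— users studying trend confounding can switch the slopes on.  The cluster
random intercept defaults to 0 (the mediation models adjust for cluster as
a covariate); a nonzero value supports the lagged-model tests.  Secondary
outcomes share the mediation structure with paths scaled by the ratio of
instrument SDs, so every outcome column behaves plausibly without extra
configuration.

For lagged-analysis testing the primary outcome can instead be generated as
an AR(1) process, `Y_{t+1} = kappa + 0.3 Y_t + theta M_t + c' T + ...`, with
cluster intercept but **no** participant intercept: with both a lagged
response and a participant intercept in the truth, short panels (T = 5)
suffer dynamic-panel (Nickell) bias, which would contaminate a recovery
check of `theta`.

Dropout is monotone (once missed, always missing; wave 1 always kept) with a
per-wave geometric hazard, independent of outcomes.  What passing tests do
*not* show about real data: scores here are continuous and Gaussian (clipping
to instrument ranges is opt-in and breaks exact recoverability), dropout is
non-informative, covariates are independent of each other and of cluster,
and mediator–outcome confounding is absent by construction — the
product-of-coefficients estimand is only causally interpretable under that
no-unmeasured-confounding assumption.

## Multivariate, sensitivity and lagged variants

The multivariate analysis fits one a-model per mediator and a single joint
outcome model on rows complete across all mediators, recording every
`a_m * b_m` within the same resample per iteration.  Sensitivity model S1
keeps mediators with univariate bootstrap p < .05 (an empty selection is a
reported status, not an error; a singleton falls back to the univariate
bootstrap); S2 keeps one mediator per construct family — resilience,
mindfulness, compassion, acceptance — choosing the smallest univariate p,
ties broken by larger |indirect| then name.  The lagged model predicts the
outcome at wave t+1 from the mediator at wave t, controlling prior outcome,
treatment (taken at the predicted wave) and wave (linear by default,
categorical behind a flag), with participant and cluster random intercepts.

## Descriptive table and multiplicity

The baseline table summarises wave-1 characteristics per cluster with
Pearson chi-square tests (no continuity correction) for categorical and
one-way ANOVA F tests for continuous variables, and applies the
Benjamini–Hochberg step-up adjustment at q = .05 within the table's family
of tests.  Mediation p-values are reported unadjusted.

## Simulation studies and problem sizes

`swmediate.validation` packages the characterisation studies used by the
test suite and the reproduction script: 50-replicate recovery of the
injected paths (full-sample fits), 200-trial type-I error of the
sign-crossing test under a null a-path and 200-trial percentile-CI coverage
at the default effects (both with 200 bootstrap iterations per trial), and
50-replicate recovery of the lagged coefficient.  These sizes give binomial
Monte-Carlo error around ±1.5 percentage points on a 5% rate and run in
minutes on a single CPU; all use the full default design of 347
participants.

## Known limitations

Wald intervals for a, b and c' ignore degrees-of-freedom corrections and can
be slightly anticonservative in small cluster counts; the bootstrap treats
clusters as fixed strata (whether to also resample clusters is a design
choice — with 6 clusters a cluster bootstrap would be extremely noisy);
random slopes, crossed random effects and non-Gaussian outcomes are out of
scope; and the percentile CI is first-order accurate only.
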