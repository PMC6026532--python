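# Methods

## Models

Every acoustic response is analysed marginally with its own mixed model.
Writing `y_ij` for the (possibly transformed) response of call `j` by
caller `i`,

    g(E[y_ij]) = b0 + b1·during_ij + b2·after_ij + b3·rank_ij
               + b4·leafclip_ij + b5·complete_ij
               + u_i0 + u_i1·c(during)_ij + ... + u_i5·c(complete)_ij

with `g` the identity (Gaussian families, response transformed first by
`sqrt`, `ln`, or `ln(1000·x)` per the registry) or the log link (Poisson
and NB2 counts). `c(·)` denotes mean-centering of the slope covariates on
the fitted rows (centered-dummy coding for the factor and binary
predictors), and the caller effects `u_ik ~ N(0, s_k²)` are independent
across terms — with five subjects a full random covariance essentially
never identifies, so independent terms are the default (a deliberate
design choice; the correlated structure is not implemented).

The null model drops the three test predictors (period, rank, leaf clip)
from the fixed part but keeps the control predictor and the *entire*
random structure, so the full-vs-null likelihood-ratio test (df = 4) only
charges the fixed effects. Single-predictor tests drop one test predictor
at a time (df 2 for period, else 1). Rows with a missing response are
removed before either fit, so nested likelihoods always share a row set.

Rank enters standardized to [0, 1] with alpha = 1, so positive
coefficients read "greater for higher-ranking males"; a flag flips the
convention. Period boundaries, when derived from dates, are the first
observed alpha–beta fight (2011-10-16) and the deposed alpha's pant-grunt
concession (2011-11-19), "during" closed on both ends.

## Estimation

All fits are maximum likelihood (never REML), making likelihood-ratio
comparisons between nested fits valid.

**Gaussian.** The marginal likelihood of `y ~ N(Xb, s²(I + Z L² Z'))` is
profiled over `b` and `s²`, leaving a bounded quasi-Newton search over the
per-term SD ratios `L` with an analytic envelope-theorem gradient. All
quantities reduce to cross-products of `X`, `Z`, `y`, so an objective
evaluation is O(q³) in the number of random-effect columns (q = 6 terms ×
callers) regardless of sample size. The profiled deviance can carry
spurious local minima where a ratio sticks to its zero boundary; after the
first solve the search restarts from the solution bumped 0.25 off every
boundary until no improvement remains.

**Poisson / NB2.** Random effects are integrated out by a Laplace
approximation at the conditional mode, found by damped Newton in the
spherical parameterization `u = L v` (smooth at variance boundaries). The
outer L-BFGS-B runs over fixed effects, per-term SDs and, for NB2, the
*inverse* shape `1/theta` bounded in [1e-4, 50]: near-equidispersed data
then terminate at a boundary instead of chasing a flat direction toward
`theta = ∞`. `theta` is re-estimated independently in every fit (full,
null, reduced). Agreement with lme4 on identical data is ~1e-4 in
log-likelihood for `lmer`/`glmer`-Poisson and ~3 decimals in coefficients
and shape for `glmer.nb` (checked in the test suite via Rscript).

**Uncertainty.** Gaussian SEs are `s²(X'V⁻¹X)⁻¹` at the ML variance
ratios. Count-model SEs take the numerical observed information over the
fixed effects *plus* all interior variance parameters and the shape, and
invert it; components estimated on their zero boundary are held fixed
(two-sided curvature is undefined there). Likelihood-ratio statistics are
clamped at zero when optimizer noise leaves a ~1e-9 negative difference; a
df-0 comparison reports p = 1.

**Fallback ladder.** A fit whose optimizer reports failure retries with
Powell from the best point, then (count models) falls back to a random
intercept only; results carry a `converged` flag and the fallback label
rather than raising. Inside the permutation loop a model that still fails
contributes p = 1 for that permutation — conservative, since it can only
shrink the permuted Fisher statistic, and counted in the result.

## The permutation omnibus

The 18 full-vs-null p-values are combined as `ts = -2 Σ ln p` (p floored
at 1e-12 against underflow). Because the tests share calls and the
responses are correlated, `ts` is calibrated by restricted permutation:
within each caller, complete 18-response row blocks are reassigned
uniformly at random to that caller's predictor rows. Blocks move jointly,
so inter-parameter correlations are retained, and missing entries travel
with their block, so each model's per-permutation sample size fluctuates
around the observed one while the marginal missingness rate is preserved.
The observed data are permutation 1 of `n_perm`; `overall_p = #{ts_perm ≥
ts_obs}/n_perm ≥ 1/n_perm`. Per-permutation randomness comes from
`SeedSequence(seed).spawn(i)`, and permutation fits warm-start from the
observed-data optimum (a fixed reference), so results are identical for
identical seed and `n_perm` regardless of execution order. A model that
fails on the observed data is excluded from all permutations and listed in
the result.

## Rate models

Daily counts are NB2 with log link and offset `ln(hours)`; coefficients
are log rate ratios per observation hour. The pant-hoot model tests
period + rank + leaf-clip day (df 4); the aggression model tests period +
leaf-clip day with rank kept as a control in both full and null (df 3).
`leaf_clip_day` is a day-level binary (the focal male was seen to leaf
clip that day), not an event count. The offset construction implies an
exact equivariance — scaling all exposures by `c` must shift only the
intercept, by `-ln c` — which the tests verify to 1e-3.

## Diagnostics

*Overdispersion*: sum of squared Pearson residuals (conditional means,
family variance `mu` or `mu + mu²/theta`) over `n - #fixed effects`; ≈ 1
for a well-specified count model. *Collinearity*: car-style generalized
VIFs on a fixed-effects-only linear model, reported as `GVIF^(1/df)` so
the 3-level period factor is df-adjusted and single-df predictors give the
ordinary VIF; exact collinearity reports `inf`. *Stability*: the full
model is refit leaving out one caller at a time; the report is the largest
absolute change across test-predictor coefficients.

## Synthetic cohort

The generator emulates the study conditions rather than idealized data:
five callers with the published per-period call counts (row sums 22, 92,
48, 21, 29; total 212); period-specific rank orders (the pre-concession
hierarchy before/during, the post-concession order after, the disappeared
male keeping his last rank); leaf-clip probability 27/212; incomplete
recordings 88/212; per-response missingness tuned so expected per-model
sample sizes match the registry's n column (212/173/189/127/210); and 68
focal days (per-male 6/22/7/9/24) with hours uniform on 3–12.5 h.

Cross-family correlation uses a Gaussian copula: one latent 18-variate
normal draw per call (default correlation 0.5 within a pant-hoot phase,
0.15 across phases, 0.3 between total duration and everything; unit
diagonal, PSD-validated) becomes correlated residuals for Gaussian
responses and inverse-CDF count draws for Poisson/NB responses. Fixed
effects default to the published study estimates where printed (e.g. leaf
clip +0.48 on `sqrt` total duration, during −0.44 on `sqrt` climax
duration, +1.17 on log drum beats) and zero otherwise; the completeness
control adds +0.3…+0.5 to durations and counts since an incomplete
recording can only lose material. Residual SDs, random-intercept SDs
(≈0.3 on each model scale, larger for Hz-scale responses) and slope SDs
(0.1) are not printed anywhere and were chosen once to give realistic
coefficient SEs at n = 212; NB shapes default to 8/3/2 for
build-up/climax/drum counts. Gaussian responses on identity or `sqrt`
scales are floored at 2% of their intercept before back-transform so
durations and frequencies stay strictly positive; the truncation touches
only the deep left tail.

What the generator does **not** emulate: informative missingness (its
missingness is MCAR per response, whereas real incomplete recordings
truncate the call itself — the completeness flag instead shifts means as a
covariate), temporal autocorrelation within days, rank dynamics beyond the
two published orders, and any waveform-level structure. Passing tests
therefore show the estimators are calibrated under the study's design and
effect sizes, not that the models are correct for any particular real
recording set.

`null_config()` zeroes every fixed effect (responses stay correlated and
caller-structured) for type-I studies. `scaled_cohort_config(k)`
replicates the whole cohort `k` times with distinct caller IDs:
calibration experiments (parameter recovery, interval coverage) run at ×3
because with only five subjects the caller-level variance components sit
on the estimation boundary and Wald intervals genuinely undercover — a
property of the five-male design, not of the fitter; the rate-model
recovery uses the same ×3 scaling (204 focal days).

## Problem sizes used by the shipped checks

Descriptives run on the published summary tables (instant). The
acceptance script simulates one 212-call / 68-day cohort, fits the full
18-model registry, and runs a 100-permutation omnibus. Calibration tests
use 50 null cohorts × 50 permutations for the omnibus type-I check
(4-model Gaussian registry), 100 replicates per family for parameter
recovery at cohort ×3, and 10,000–18,000 draws for the permutation
uniformity checks. These sizes were chosen so the whole battery runs on a
single CPU in well under half an hour while keeping Monte-Carlo bands
tight enough to detect real miscalibration.

## Known limitations

* Inference conditions on the chosen model set; no model selection, AIC,
  or Bayesian machinery is provided.
* Wald SEs for count models use the Laplace-approximate likelihood; with
  very small counts and strong overdispersion the Laplace logLik itself
  carries a small bias (a few hundredths of a log unit against lme4's
  implementation on the study scale).
* Even at cohort ×3, 2-SE Wald coverage for the lowest-noise count family
  (the Poisson intro-call model) runs at ≈93% rather than the nominal
  95.4% — estimates are unbiased and reported SEs match the empirical
  spread to within a few percent, but variance components estimated at
  their zero boundary and the finite number of callers fatten the tails of
  the coverage distribution. The shipped recovery check reports the
  observed hit count directly.
* The omnibus treats a permutation-failing model as p = 1, which is
  conservative; heavy failure rates (logged in the result) would deflate
  power.
* The behavioural-activity control models mentioned as optional in the
  source analyses are not implemented.
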