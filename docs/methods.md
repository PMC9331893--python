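# Methods

## The analysis

A *specification* is one complete analytic choice: an outcome y (one of
three relationship scale totals), a predictor x (one of 20 smartphone
content-frequency items) and a covariate set C drawn from {gender, grade,
subjective SES, objective SES, daily screen time}. Every variable is
standardized (sample mean 0, SD 1, denominator n−1) before any model is
fit, so regression coefficients are standardized βs. Each specification is
an OLS fit of z(y) on an intercept, z(x) and z(C); the package records β,
its standard error, t = β/se, residual df = n − k − 1, the two-sided
p-value from the t distribution (exact under normal errors; at survey n
indistinguishable from the normal), the 95% CI β ± t₀.₉₇₅,df·se, and the
partial r² = t²/(t² + df) — the share of outcome variance uniquely
attributable to the predictor given the covariates.

The default design crosses 20 predictors × 3 outcomes × 7 covariate sets.
The seven covariate sets are the lattice {no controls} ∪ {each of the five
single controls} ∪ {all five controls}; the class of "reasonable" control
sets is a genuinely open design choice, and this lattice is the only
symmetric reading that yields seven sets from five covariates. Explicit
set lists can be supplied instead (config key `covariate_sets`, CLI flag
`--covariate-sets`).

Per predictor, the 21 specifications are summarized by

* **median β** — middle element for odd counts, mean of the middle two for
  even counts (the default per-predictor curve has 21 specifications, so
  the median is an actual fitted specification);
* sign/significance counts at level α (default 0.05);
* **NSRPD** — the number of specifications with p < α whose β carries the
  sign of the median β (a median of exactly 0 is resolved toward the side
  with more significant results; the rule is tested);
* partial r², reported two ways because the convention is ambiguous: the
  value at the median-β specification (primary; for even counts, the lower
  middle element) and the median of the per-specification partial r²s.
  A partial r² ≥ 0.01 (the predictor uniquely explaining ≥ 1% of outcome
  variance) is flagged; the flag is inclusive at the boundary while
  significance stars use strict inequalities (\* p < 0.05, \*\*\* p < 0.001).

## Forced-null bootstrap inference

For each specification the fitted effect is removed from the outcome:
y\* = y − β̂x. By OLS linearity, refitting the specification on y\* returns
a predictor coefficient of exactly zero (the test suite asserts < 1e−10
across the full 420-specification battery), so the null hypothesis holds
*exactly* in the forced-null data while the covariate structure,
measurement error and inter-item correlations are preserved. Each
bootstrap cycle draws n participants with replacement (one draw shared by
the whole curve), refits every specification on its own forced-null
outcome, and records that cycle's median β and NSRPD; the default is 500
cycles. The NSRPD inside a bootstrap curve uses that curve's own dominant
sign and the same α as the main analysis.

P-values use the add-one convention — two-sided for the median,
p = (1 + #{|median\*| ≥ |median|})/(B + 1), one-sided for the NSRPD — so a
finite bootstrap never reports p = 0 and p is monotone in the observed
statistic. Inference is per predictor by default (matching per-content
reporting); `scope="curve"` pools all specifications into one null.
Variables are standardized once on the full data before resampling, not
re-standardized within each resample; re-standardizing would only rescale
each bootstrap fit by a factor that converges to 1 and would break the
exact-zero property of the forced null.

The hot loop computes every OLS fit from the resample's cross-product
(gram) matrix — one n × (1 + r + m) matrix product per cycle for r
distinct regressors and m specifications, then m small Cholesky solves.
This is algebraically identical to the per-specification fit and is
cross-checked against it in the tests. A degenerate resample (collinear
regressors) is redrawn, counted, and capped at 1,000 redraws.

## Missing data

**Little's MCAR test.** Rows are grouped by missingness pattern j; the
statistic is d² = Σⱼ nⱼ (ȳ_obs,j − μ̂ⱼ)ᵀ Σ̂ⱼ⁻¹ (ȳ_obs,j − μ̂ⱼ), with (μ̂, Σ̂)
the EM maximum-likelihood estimates (denominator n) and Σ̂ⱼ the submatrix
for pattern j's observed variables; under MCAR d² ~ χ² with Σⱼ pⱼ − p
degrees of freedom. Complete data is the one-pattern degenerate case
(χ² = 0, df = 0, p = 1). Rows missing every variable are dropped with a
logged count; a singular pattern covariance falls back to the
pseudo-inverse and is flagged in the result.

**EM imputation.** Multivariate-normal EM: the E-step computes, per
pattern, the conditional means and cross-moments of the missing block
given the observed block; the M-step updates (μ, Σ). The observed-data
log-likelihood is computed each iteration and asserted non-decreasing (to
a 1e−6 relative slack for round-off); convergence is an improvement below
`tol` (default 1e−5 in the transformer, 1e−4 in the pipeline, on the
log-likelihood scale), capped at `max_iter` with a logged warning rather
than an error. Missing cells are replaced by conditional means at the
converged parameters; observed cells are never altered. Imputed Likert
values are deliberately left continuous — downstream analysis is linear
regression on standardized variables, and rounding back to {1..4} would
only add noise. Single imputation is used throughout; the conditional-mean
fill understates variance, which is acceptable because the imputation feeds
point estimation, not interval construction. EM runs jointly at item level
over all analysis variables (content items, scale items, covariates); the
alternative of scale-level EM was rejected because item-level missingness
is what the generator produces and what real surveys show.

Pipeline order is fixed: exclusions (smartphone ownership first, then
incompleteness — rows missing ≥ 50% of analysis variables, both counts
logged) → Little's test (diagnostic only; its outcome does not gate the
EM step) → EM imputation → scale scoring (totals of 11, 10 and 5 items)
→ standardization.

## The synthetic-survey generator

The generator emulates the structure the analysis assumes, at the
composition of the motivating survey: N = 46,018 by default, P(grade 8) =
34,578/46,018, P(male) = 23,946/46,018, mean missing rate 4.15%.

* **Content items.** Latent propensities are equicorrelated standard
  normals (common-factor construction), cut at `likert_thresholds` into
  {1..4}. The default intercorrelation of 0.4 puts the observed 20-item
  Cronbach's α near 0.9, in the range instruments of this kind report.
  Thresholds default to standard-normal quartiles (symmetric marginals) —
  a neutral choice, since no item distributions are available to match.
* **Outcome scores.** The latent score for outcome j is
  Σₖ bₖⱼ·z(xₖ) + Σ γⱼc·z(c) + ε, with z(·) the standardized *observed*
  (discretized) items, and ε scaled so the latent score has unit sample
  variance (configurations whose systematic variance reaches 1 are
  rejected). Effects are therefore standardized regression effects of the
  observed content items on the latent outcome.
* **Scale items.** Each of the 11/10/5 items is λ·latent + √(1−λ²)·noise,
  discretized by the same thresholds. The common loading λ = 0.75 gives
  observed-scale reliabilities near 0.9. A single common loading cannot
  reproduce three different scale reliabilities at once; per-scale
  loadings were deliberately not added, as nothing downstream depends on
  the scales differing.
* **Covariates.** Gender and grade are Bernoulli at the survey
  composition; subjective SES (1–5) and screen time (0–7) discretize
  standard normals at equal-probability cuts; objective SES is standard
  normal (it models a mean of standardized income/education scores).
  Covariate effects on outcomes default to zero.
* **Calibration.** Discretizing the scale items attenuates the observed
  standardized slope below the configured latent effect (by ~10% at the
  defaults). `calibrate_effects` bisects on a fixed-seed calibration
  sample (default n = 100,000, internal seed fixed so calibration is
  reproducible and monotone via common random numbers) until the
  post-discretization marginal slope matches the target within 1e−3.
  Each entry is calibrated in isolation, which is exact when each outcome
  has at most one nonzero effect and approximate otherwise (cross-talk
  through content intercorrelation is ignored).
* **Missingness.** MCAR masks every analysis cell independently
  (`participant_id` and the optional ownership flag are exempt) — MCAR is
  the correct null for validating Little's test and the EM step even
  though real survey data typically rejects it. The MAR mode gives
  grade-8 rows twice the per-cell missing probability of grade-4 rows
  (rescaled to the requested overall rate; the driver column is never
  masked) and exists to demonstrate the Little's-test power the MCAR null
  cannot.

What the generator does **not** emulate: school-level clustering and the
two-stage stratified sampling of a real assessment (so standard errors on
real data would be optimistic relative to the simulation), item-response
(graded response) measurement, skewed item marginals, and
missingness-on-outcome mechanisms. Passing tests therefore certify the
*procedure* — enumeration, estimation, null calibration, recovery — under
a clean factor-model world, not the substantive conclusions one would
draw from any real survey.

## Problem sizes and numerical choices

Test and acceptance runs use deliberately scaled problem sizes: n = 400
for fixtures, n = 1,000 with 200 bootstrap cycles × 100 replicates for the
median-test type-I-error calibration (observed rejection rate must lie in
[0.01, 0.11] at α = 0.05), n = 5,000 × 50 replicates for recovery of a
planted 0.12 effect, n = 500 × 200 replicates for Little's-test
calibration and n = 2,000 × 20 for its MAR power. These sizes keep the
full suite in the minutes range while leaving the Monte-Carlo bands
meaningful. Determinism: all randomness flows through
`numpy.random.default_rng` seeds; per-predictor bootstrap seeds are
spawned from the master seed via `SeedSequence` in predictor order, so
results are independent of which predictors are requested together.

OLS uses a QR factorization with a rank check (relative diagonal
threshold 1e−10; collinear or constant regressors raise with the offending
specification named); a perfect fit (zero residual variance) reports
p = 0 and partial r² = 1 rather than dividing by a zero standard error.
Grade {4, 8} and gender {0, 1} enter regressions through standardization
directly, which for a two-level variable is identical up to sign and scale
to standardizing a 0/1 dummy. Under the all-null generator the share of
significant specifications is asserted as an average over replicate
datasets, because the 420 p-values of one dataset cluster into about 60
effective tests and the single-dataset share is far noisier than the
nominal binomial band suggests.

## Known limitations

* Whole-curve inference treats the 420 specifications as one family; no
  between-predictor multiplicity correction is offered beyond it.
* The EM imputer assumes joint normality of ordinal items — standard
  practice, but a misspecification by construction; its benchmark
  guarantees (mean recovery within ±0.05 on the ρ = 0.8 bivariate case)
  are about the algorithm, not about ordinal data fidelity.
* The calibration routine's single-entry isolation makes dense effect
  matrices only approximately calibrated.
* Confirmatory factor analysis of the scales (fit indices such as
  CFI/TLI/RMSEA) and survey weighting are out of scope.
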