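# Methods

## The comparison problem

The package quantifies the *incremental* predictive value of biomarker
panels added to a baseline cardiovascular risk score for a dichotomized
coronary-artery-calcification (CAC) outcome. Two nested logistic models are
fit on an identical case set and compared on four axes: ranking ability
(AUC, with a paired test for the correlated difference), category
reclassification (NRI), probability-scale separation (IDI), and calibration
(Hosmer–Lemeshow). Models are built on a random half of the cohort and
assessed both on that half and, with frozen coefficients, on the held-out
half.

## Statistics

**Mann–Whitney AUC and DeLong inference.** The AUC is the proportion of
event/non-event pairs ranked correctly, ties counting ½, computed via
midranks in O(n log n). Its variance uses the DeLong structural components:
for event *i*, V10ᵢ is the proportion of non-events ranked below it (ties
½), and symmetrically V01ⱼ for non-events; then
`var(AUC) = var(V10)/m + var(V01)/n`. For two models scored on the same
cases, the variance of ΔAUC replaces the marginal variances with the 2×2
covariance matrices of the paired components, giving a normal z-test. A
comparison of a model with itself has zero variance and zero difference and
returns p = 1 by convention; zero variance with a nonzero difference is an
error.

**NRI.** Two categories split at a risk threshold t (default 0.5, with
p ≥ t high risk — the boundary is high). Among events, the net proportion
moving up; among non-events, the net proportion moving down; the NRI is the
**sum** of the two nets, with range −2 to +2. The standard error is the
binomial-difference form
`sqrt[(P̂up,e+P̂down,e)/n_e + (P̂up,ne+P̂down,ne)/n_ne]`. Some published
formula displays join the two brackets with a minus sign; the sum form is
the standard definition (and the one consistent with "net improvement in
both strata") and is what this package implements.

**IDI.** The difference of the mean change in predicted probability between
events and non-events, equal to the difference of the integrals of
sensitivity and 1−specificity over all cutoffs (verified as a test
invariant by trapezoidal integration). SE from the within-group SDs of the
paired differences.

**Hosmer–Lemeshow.** Cases sorted by predicted probability and cut into
g near-equal groups (default deciles); tied probabilities are kept together
in the lower group, so a large tie block can make groups uneven. Both the
event and non-event cells contribute to the chi-square; df = g − 2, the
convention for development-sample calibration. Probabilities must be
strictly inside (0,1); predictions are clipped to [1e-10, 1−1e-10] because
saturated linear predictors otherwise produce exact 0/1 in floating point.

**Logistic engine.** Unpenalized maximum likelihood by
Newton/IRLS with step-halving (the log-likelihood path is non-decreasing by
construction), convergence at relative log-likelihood change < 1e-10 or
gradient < 1e-9, at most 100 iterations. Standard errors come from the
inverse observed information. Separation is declared when coefficients
exceed 15 in absolute value — during iteration with a non-vanishing
gradient, or at convergence with a saturated likelihood — and raises rather
than returning a meaningless fit. The pipeline (only) retries separated
fits with a weak L2 penalty (1e-2): in repeated ~70-case subsets with
several predictors, quasi-separation is an occasional nuisance, not a
modelling failure; library users calling `fit_logistic` directly keep the
error by default.

## Selection procedure

Markers enter models as natural-log concentrations standardized to unit
variance, with standardization constants learned on the training half and
reapplied to the validation half. The univariate screen fits one logistic
model per marker (on its available cases; MRM markers exist only in an
assayed subset) and flags Wald p < α = 0.05; constant or separating markers
are reported non-estimable and never flagged. Stepwise selection is forward
entry of the smallest-p candidate below `p_enter` (ties broken on p, then
name) followed by backward removal of any term above `p_remove`, defaults
0.05/0.10. With k inert candidates the probability that the best null
p-value beats 0.05 in a step is ≈ 1−0.95^k, so exact recovery of a true
subset needs stringent thresholds; the test suite exercises both regimes.
The four nested specifications are reference (score alone), +ELISA panel,
+MRM panel, +both; each comparison fits reference and new model on the
complete cases of the union of their predictors, so both ROC curves derive
from the same cases.

## Synthetic cohort generator

The generator emulates the structure of a pooled RA clinic cohort
(n = 561): age ~ N(57.6, 10.5²) years, 77% female, 42% hypertensive, 14%
current smokers. One latent atherosclerosis liability L drives everything:

- L = (standardized covariates · weights) + N(0,1), standardized by its
  theoretical SD;
- the baseline risk score is expit(−1.9 + 1.1·(L + ν)) with measurement
  noise ν ~ N(0, 1.10²) — the noise scale, not pooled-cohort coefficients,
  fixes the score's stand-alone discrimination (AUC ≈ 0.78 for CAC>100);
- each marker's standardized log concentration is
  (effect·L + √0.2·F + √0.8·ε)/√(1+effect²), with one shared factor F
  giving a 0.2 background inter-marker correlation; `effect` = 0 is inert.
  Defaults: 8 signal ELISA markers (effects 0.30–0.90, the four strongest
  mirroring the panel a stepwise selection typically retains), 3 signal MRM
  peptides (|effects| 0.75–0.85, two protective), 12 inert ELISA markers;
- CAC is two-part: positive with probability expit(0.325 + 2.0·L), and then
  lognormal with log-mean 3.936 + 1.6·L and log-SD 1.0; otherwise exactly 0;
- MRM columns are missing completely at random for all but a 140/561
  fraction of patients (one shared assayed subset — the subset reflects
  assay cost, not patient characteristics).

**Calibration.** The two intercepts are the handles that pin the prevalence
profile: bisection on smooth expected prevalences over a seeded probe
sample sets the zero-part intercept to match P(CAC>0) = 0.55 and the
log-mean intercept to match P(CAC>100) = 0.30; P(CAC>300) is then
determined by the slopes and log-SD and is verified against 0.16 (±0.01),
erring with the best-achieved values if the shape cannot reach the targets.
The slope/SD defaults were chosen once so all three targets are
simultaneously reachable — the spacing of the >100 and >300 cut points
pins the effective spread of log-CAC among positives at ≈1.65. Default
intercepts are stored at their calibrated fixed point, so
`calibrate_cac_intercepts(default_params())` is a no-op up to bisection
tolerance.

Because score and markers are noisy readouts of the same liability,
biomarkers carry genuine information beyond the score, and adding them
yields the qualitative pattern of interest: little movement in AUC, clear
positive IDI. What the generator does **not** emulate: treatment effects,
center heterogeneity, informative MRM missingness, non-lognormal marker
distributions, and marker–covariate correlation beyond the liability
channel. Passing tests therefore demonstrate correctness of the statistics
and the pipeline under a plausible data-generating law, not performance of
any particular biomarker panel on real patients.

## Numerical and design choices

- Outcome dichotomization is strict (`>` 100, `>` 300); the boundary value
  is a non-event.
- Default split sizes are ⌈n/2⌉/⌊n/2⌋; uneven explicit sizes (e.g. 284/277)
  are accepted as arguments. The split is unstratified by default, with
  optional stratification on a binary column.
- Validation-half metrics use training-fit coefficients (honest external
  validation); `refit_validation` reproduces the refit reading.
- Missing covariate or score values are rejected rather than imputed;
  only markers may be missing, and complete-case subsetting per model (or
  per comparison union) handles them.
- Screening/selection run at the lower outcome threshold (the primary
  endpoint) and the selected panels are frozen for all reported models.
- Wald tests throughout screen/stepwise; NRI/IDI confidence intervals are
  asymptotic Wald; DeLong CI on the AUC scale, clipped to [0,1].
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; two runs with identical config and seed are
  byte-identical.

## Problem sizes used in the checks

Prevalence and AUC calibration use n = 100,000 and n = 50,000 cohorts;
type-I-error simulations use 1,000 replicates (n = 500 for the paired AUC
test, n = 1,000 for Hosmer–Lemeshow); the null-reclassification and
parameter-recovery checks use 500 replicates (n = 561 and n = 5,000); the
end-to-end pattern check runs the full pipeline on 100 study-sized cohorts.
These sizes keep Monte-Carlo error comfortably inside the asserted bands.

## Known limitations

- The two-category NRI at a single 0.5 threshold is the only NRI variant;
  multi-category and continuous NRI(>0) are out of scope.
- The Hosmer–Lemeshow test is applied with g−2 df on both halves; the
  validation-half df convention varies across texts.
- Stepwise selection on screened candidates inherits the usual instability
  of stepwise procedures at modest n; the pipeline reports the selection
  trace so it can be inspected.
- The generator's MRM missingness is completely at random by design; if
  real missingness were outcome-related, complete-case comparisons would be
  biased in ways these simulations cannot reveal.
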