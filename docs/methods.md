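# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the design decisions taken where more than one
reasonable convention exists. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator

The generator (`epiaging.simulate`) emulates a prospective cohort
followed from late childhood into adulthood with repeated blood-based
methylation assessments.

**Design.** Each subject contributes 1–3 waves; the default mix
(27.1% / 54.9% / 18.0% for 1 / 2 / 3 waves) reproduces a cohort of 539
subjects with 1029 assessments, i.e. 1.9 per subject. Single-wave ages
are uniform on 9–35 y; multi-wave subjects get childhood waves 1–3 y
apart below age 16.5 and one adult wave drawn ~N(10.74, 4.04²) years
after the last childhood wave, clipped into [18, 35]. Tanner stage is
a noisy monotone function of age in childhood and fixed at 5 for adult
rows. Cell-type proportions (CD3⁺, CD14⁺, CD15⁺, CD19⁺) are Dirichlet
around typical whole-blood composition; two standard-normal technical
covariates stand in for batch/lab structure.

**Latent aging deviation.** d_ij = u_i + w_ij in years, with
subject-stable u_i and wave-specific w_ij zero-mean Gaussian. Defaults:
total SD 1.5 y split 50:50 (aging_icc = 0.5). The motivating cohort
literature does not report the variance of epigenetic aging itself, so
this is a free parameter chosen to sit plausibly between clock error
(~1.5–2 y MAE) and the restricted age range; it is set once and not
calibrated further.

**Risks.** Each risk has a standardized latent
z = √icc·a_i + √(1−icc)·e_ij whose subject component correlates
ρ_subject with u and whose wave component correlates ρ_wave with w
(risks mutually independent given the aging latents; the implied joint
correlation matrix is checked for positive semi-definiteness). The
latent is pushed through the family's quantile function (Gaussian
copula): Poisson for counts, Gaussian for continuous, thresholding for
binary. The Pearson targets are exact on the latent/continuous scale;
quantile mapping attenuates them slightly for count and binary
margins, which is why recovery checks use continuous risks and the
stored latents. Default battery: four symptom/exposure counts
(depressive, anxiety, trauma, impairments), BMI (continuous,
ICC 0.7 — the most stable risk), and four binary lifestyle/adversity
indicators, with default couplings ρ_subject = 0.15 for BMI and a
1.67 months/symptom lagged depressive effect, all else null.

**Lagged effect.** For subjects with a pre-adult and an adult wave, the
adult deviation gains (b/12)·exposure_T2, where exposure_T2 is the
cumulative (rolling-sum) childhood value for count risks and the
observed T2 value otherwise — exactly the quantity the downstream
change-score model regresses on, so the injected b is the estimand.

**Methylation.** score_sj = baseline_s + slope_s·(age_j + d_j − 22) +
offset_si + covariate loadings + noise, clamped to [0, 20] (optional
integer rounding). Defaults: 400 sites of which 100 carry true age
slopes ~N(0, 0.08²) score-units/year, baselines uniform on [4, 16],
subject-stable offsets SD 0.5, i.i.d. noise SD 1.0. The site count is
scaled down ~5 orders of magnitude from a real affinity-capture assay;
what is preserved is the structure that matters for the clock — a
minority of informative sites among noise, subject-stable nuisance
variation, and covariate-linked structure — not genomic realism. The
generator does not simulate reads, coverage, site dropout, or CpG
coordinates, so passing tests say nothing about read-level QC.

Identical config + seed gives bit-identical output; all draws come from
one `numpy` Generator.

## Clock

Per training fold: (1) sites ranked by |t| of per-site OLS of score on
age (ties broken by site ID for determinism; zero-variance sites get
t = 0); (2) site count grown along the grid (default 50, 100, 200, 400
capped at the matrix size); at each count the ridge penalty is chosen
from a log-spaced grid (10⁻²…10⁴, 7 points) by 5-fold inner CV grouped
by subject, scoring pooled out-of-fold predictions with the
bias-penalizing R²; (3) the search stops when R² fails to improve by
more than 10⁻³ and the previous count is kept (the grid is finite, so
the rule always terminates; monotonicity is not assumed); (4) the
chosen model is refit on the whole training fold and predicts the held
fold. Features are standardized to training-fold mean 0 / SD 1 because
ridge penalties are scale-sensitive. Inner ridge paths are computed
from one SVD per inner fold (all penalties at once), matching
scikit-learn's `Ridge` solutions; the final per-fold model is a
scikit-learn `Ridge` fit.

Folds partition *subjects*, never assessments: repeated measures share
subject-stable methylation, and splitting a subject across train and
test would leak it. `check_no_subject_leakage` enforces this, and the
permutation test in the validation suite confirms out-of-fold r ≈ 0
when ages are shuffled. Covariates are excluded from the predictor set
by default (the clock sees only methylation); a covariate-adjusted
site scan is possible by residualizing scores upstream.

**Attenuation.** Ridge shrinkage plus site-level noise compress
predicted-age variation: the regression slope of DNAm age on biological
age is below 1. Consequently downstream estimates that use clock output
(subject-level correlations, lagged coefficients) are attenuated
relative to the generator's latent-scale truth. Validation therefore
separates concerns: estimator-recovery checks feed the analysis modules
the ground-truth deviations (a perfect clock), while full-pipeline runs
report the attenuated values honestly.

## Epigenetic aging and derived quantities

* **Residualization** is OLS of DNAm age on an encoded design
  (intercept; age + age² when configured; one-hot categoricals with
  reference level). Rank deficiency raises an error naming the
  collinear columns (pivoted QR). Because the cell proportions sum to
  1, the granulocyte fraction (CD15⁺) is the omitted reference in all
  default covariate sets.
* **Winsorization** clamps values beyond mean ± 3·SD to the threshold,
  with mean/SD computed once from the input (no re-estimation);
  zero-variance input passes through. Applied to continuous variables
  only, after wave filling and before modeling.
* **Wave filling**: count/binary exposures use a rolling sum across
  observed waves (missing waves contribute 0 — absence of a report is
  treated as absence of exposure, and the value becomes a cumulative
  exposure); variables that cannot be zero (BMI) use the subject mean.
  An all-missing subject is an error, not an imputation.
* **FDR**: Benjamini–Hochberg step-up via `statsmodels.multipletests`,
  validated in tests against a brute-force implementation of the
  step-up definition.

## Bivariate mixed model

Stacked two-response formulation with subject random intercepts:
V_i = I_{n_i} ⊗ R + J_{n_i} ⊗ G (responses interleaved per wave).
Fixed effects are response-specific (each covariate gets a slope per
response, plus per-response intercepts).

* **Estimation** is ML by default (REML optional). G and R are
  parameterized by Cholesky factors with log diagonals, which enforces
  positive definiteness and makes the G₁₂ = 0 / R₁₂ = 0 constraints a
  single fixed parameter. β is profiled out by GLS inside every
  likelihood evaluation; since V_i depends only on n_i, each wave-count
  group shares one inverse and log-determinant.
* **Starting values** are ANOVA-type moment estimates (pooled
  within-subject SSCP for R; covariance of subject means minus R over
  the harmonic mean wave count for G, eigen-clipped to PD). The fitted
  log-likelihood is checked to be at least the starting value.
* **Optimization**: L-BFGS-B with numerical gradients, log-diagonals
  bounded in [−10, 10], at most 500 iterations; non-convergence is
  flagged, never silently returned.
* **Inference**: 1-df likelihood-ratio tests for each cross-covariance,
  warm-started from the full fit. LRT is preferred to Wald because
  covariance parameters near the boundary make Wald unreliable. A
  50:50 mixture correction is available but off by default — the tested
  parameter is a covariance, not a variance bounded at zero. Component
  correlations with |ρ| > 0.995 raise a boundary flag and suppress the
  tests (degenerate likelihood). On balanced 2-wave data the ML fit has
  a closed form (R̂ = SSW/(N(n−1)), Ĝ = (SSB/N − R̂)/n), used as an
  independent oracle in the validation suite.
* Binary risks enter the Gaussian bivariate model on the 0/1 scale
  (linear-probability treatment), noted in the output table.

The decomposition table reports, per risk: both ICCs, r_total,
r_subject, r_wave (which sum exactly to r_total because T = G + R by
construction), LRT p-values and BH-FDR across risks (separately per
level). A significant wave-level contribution is necessary but not
sufficient for a causal reading; the module reports decompositions
only.

## Lagged change-score models

T2 is the latest pre-adult assessment (< 17 y; later ones capture the
largest cumulative exposure history), T3 the adult assessment (≥ 17 y;
the earliest if several, logged). The forward model is OLS of ΔDNAm
age (years) on exposure_T2, adjusting for Δage, adult age, sex,
race/ethnicity, and adult + Δ cell/technical covariates; with Δage and
adult age in the model the coefficient measures age-adjusted change,
i.e. epigenetic aging. Coefficients are ×12 into months (the month and
year scales are exact multiples); CIs are Wald ±1.96·SE. The fully
adjusted variant adds adult and Δ values of BMI, smoking, cannabis and
alcohol. The ten-or-so forward models form one BH-FDR family; reverse
models (pre-adult epigenetic aging → change in risk, adjusting for the
T2 risk value; coefficient in risk units per year) form a separate
family. Δ Tanner stage is not among the lagged covariates (adult rows
are all stage 5, so the delta is nearly collinear with Δage).

Percentile summaries evaluate the fitted model at empirical percentiles
of the exposure with all other covariates at sample means, reporting
both the absolute predicted change (dominated over a ~10-year follow-up
by ordinary chronological aging) and the change relative to the
prediction at the mean exposure — the "months older than expected"
reading.

## Problem sizes and tolerances in the validation suite

The suite favors configurations that make Monte-Carlo error small
relative to the checked bands while keeping a full run in a few
minutes: balanced-oracle equivalence at 200 subjects (tolerance 1e-3,
optimizer-limited); decomposition recovery at 1000 subjects × 2 waves
averaged over 10 seeds (±0.05); LRT type-I calibration with 500
replicates at 300 subjects (95% binomial band around 0.05); lagged
recovery at 380 pairs × 10 seeds (±0.3 months) with a 500-replicate
null; 20 age-permutation clock refits at 300 subjects. Generator
configs for estimator checks set `n_sites=0` (no methylation needed)
and feed the analysis modules the ground-truth deviations, isolating
estimator error from clock attenuation.

## Known limitations

* The copula hits Pearson targets exactly only for continuous margins;
  count/binary couplings are mildly attenuated by quantile mapping.
* The generator has no site dropout, no missing methylation cells, no
  family structure, and no genetic confounding; risk missingness is
  optional and independent at random.
* Binary risks in the bivariate model use a linear-probability
  treatment rather than a threshold model.
* The bivariate model fits exactly two responses with random
  intercepts only — no random slopes, no autoregressive wave
  residuals, no three-way decompositions.
* Full-pipeline effect estimates are attenuated by ridge shrinkage in
  the clock (see above); comparisons across clocks with different
  shrinkage are not calibrated.
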