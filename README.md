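# epiaging

Longitudinal analysis of epigenetic aging and health risks: a
cross-validated DNA-methylation age clock, a bivariate mixed model that
splits the aging–risk covariance into between-person and within-person
parts, and lagged change-score models linking childhood exposures to
adult epigenetic aging — together with a synthetic-cohort generator
that provides ground truth for every stage.

## The problem

Cross-sectional studies keep finding correlations between "epigenetic
age acceleration" and health risks (depression, BMI, smoking,
adversity), but a correlation at one time point cannot say whether a
risk makes the clock *tick faster*. With repeated methylation
assessments on the same people — here, semi-quantitative
methyl-CpG-binding-domain sequencing scores on a 0–20 scale, collected
from late childhood (~age 9) into adulthood (~age 35) — two sharper
questions become answerable:

1. **Concurrent:** when a person's risk level changes from wave to
   wave, does their epigenetic aging change with it (within-person), or
   is the association carried entirely by stable differences between
   people?
2. **Lagged:** does exposure in childhood/adolescence predict how much
   *older than expected* a person's methylome has become by adulthood?

This package implements that full analysis for long-format cohort
tables, and — because the motivating cohort data are controlled-access
— validates every stage against a generator with known ground truth.

## Models

**Clock.** Chronological age is predicted from methylation scores by
ridge regression inside subject-grouped 10-fold cross-validation. In
each training fold, sites are ranked by the |t| statistic of a per-site
regression of score on age, the number of top sites is grown stepwise
until inner-CV predictive power stops improving, and the penalty λ is
chosen by inner cross-validation. All assessments of a subject share a
fold, so out-of-fold predictions (*DNAm age*) are unbiased. Accuracy is
summarized by MAE, Pearson *r*, a bias-penalizing
R² = 1 − Σ(ŷ−y)²/Σ(y−ȳ)², and MAE_weighted = MAE / age range.

**Epigenetic aging** is the OLS residual of DNAm age on chronological
age (linear + quadratic), sex, Tanner stage, race/ethnicity, cell-type
proportions and technical covariates — positive values mean
biologically older than expected.

**Covariance decomposition.** For epigenetic aging y₁ and one risk y₂
measured at waves j within subjects i:

    (y₁ᵢⱼ, y₂ᵢⱼ)ᵀ = Xᵢⱼβ + uᵢ + eᵢⱼ,  uᵢ ~ N(0, G),  eᵢⱼ ~ N(0, R)

with unstructured 2×2 G (subject level) and R (wave level), estimated
by maximum likelihood with Cholesky-parameterized covariances (written
from scratch; β profiled out by GLS). The total covariance T = G + R
yields standardized contributions r_subject = G₁₂/√(T₁₁T₂₂) and
r_wave = R₁₂/√(T₁₁T₂₂) which add exactly to the total correlation, and
ICCs G₁₁/T₁₁, G₂₂/T₂₂ measuring stability over time. Each contribution
gets a 1-df likelihood-ratio test; Benjamini–Hochberg FDR is applied
across risks.

**Lagged models.** Each subject's latest pre-adult assessment (T2,
age < 17) is paired with the adult assessment (T3). OLS regresses
ΔDNAm age (T3 − T2, years) on the T2 exposure (cumulative rolling sum
for count/binary risks, winsorized value for continuous ones),
adjusting for Δage, adult age, demographics and cell/technical
covariates; the slope ×12 is reported in months per risk unit, with a
fully adjusted variant adding lifestyle covariates and percentile
summaries of the predicted change.

## Worked example

```python
from epiaging import (SimulationConfig, generate_cohort, MethylationClock,
                      epigenetic_aging, decomposition_table, build_pairs,
                      LaggedChangeModel, percentile_effects, CONCURRENT_COVARIATES)

cfg = SimulationConfig(seed=1)                      # 539 subjects, ~1.9 waves each
cohort, meth, truth = generate_cohort(cfg)

clock = MethylationClock(meth, cohort, k=10)
res = clock.fit(seed=1)
print(res.summary())
```

```
Cross-validated methylation-age clock
=============================================
assessments: 1023   folds: 10
site grid: [50, 100, 200, 400]
chosen site counts per fold: [100, 100, 100, 100, 100, 100, 100, 100, 100, 100]
MAE:             1.563 years
MAE_weighted:    0.060
Pearson r:       0.957
R^2:             0.914
```

Out-of-fold predictions track chronological age closely (r = 0.96,
typical error ~1.6 years); every fold's stepwise search settled on 100
sites. Decomposing the covariance between epigenetic aging and BMI:

```python
aging = epigenetic_aging(cohort, res.dnam_age)      # residualized DNAm age, years
families = {r.name: r.family for r in cfg.risks}
table = decomposition_table(cohort, aging, ["bmi"], families,
                            covariate_cols=list(CONCURRENT_COVARIATES),
                            quadratic_age=True)
```

```
risk  icc_aging  icc_risk  r_total  r_subject  r_wave  p_subject  p_wave
 bmi      0.287     0.674    0.052      0.029   0.023      0.399   0.297
```

BMI is highly stable over time (ICC 0.67); at this sample size the
small subject-level correlation built into the generator is attenuated
by clock prediction error and does not reach significance. The lagged
model for depressive symptoms:

```python
pairs = build_pairs(cohort, res.dnam_age, families, aging=aging)
fit = LaggedChangeModel(pairs, "depressive_symptoms", "count",
                        fully_adjusted=True).fit()
print(fit.summary())
print(percentile_effects(fit, percentiles=(1, 50, 99)).round(2))
```

```
forward lagged model for depressive_symptoms (fully adjusted, n=395)
  b = 0.798 months/unit  SE = 0.505  95% CI [-0.195, 1.792]  p = 0.115
 percentile  predictor_value  predicted_change_months  relative_change_months
        1.0              0.0                   115.33                   -3.51
       50.0              4.0                   118.52                   -0.32
       99.0             14.0                   126.51                    7.67
```

Each symptom of cumulative childhood depression predicts ~0.8 extra
months of epigenetic aging by adulthood in this replicate (the
generator's true effect, 1.67 months/symptom, is partly compressed by
ridge shrinkage in the clock — see `docs/methods.md`). A child in the
99th symptom percentile is predicted to arrive at adulthood ~7.7 months
biologically older than the cohort expectation; the absolute predicted
change (~116–127 months) is dominated by the ~10-year follow-up gap
itself.

The same pipeline is scriptable from a shell:

```
epiaging simulate --config cfg.yaml --out sim/ --seed 1
epiaging train-clock --meth sim/methylation.tsv --cohort sim/cohort.tsv --out clock/
epiaging concurrent --cohort sim/cohort.tsv --predictions clock/predictions.tsv \
    --risks bmi,depressive_symptoms --out conc/
epiaging lagged --cohort sim/cohort.tsv --predictions clock/predictions.tsv \
    --risks depressive_symptoms --fully-adjusted --plot-risk depressive_symptoms --out lag/
```

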