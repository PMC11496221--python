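"""Pair construction, lagged change-score models, percentile effects."""

import numpy as np
import pandas as pd
import pytest

from epiaging import (LaggedChangeModel, RiskSpec, SimulationConfig,
                      build_pairs, generate_cohort, lagged_table,
                      percentile_effects)
from conftest import perfect_clock_dnam


def make_cohort(rows):
    df = pd.DataFrame(rows)
    df["assessment_id"] = [f"a{i}" for i in range(len(df))]
    return df


def dnam_series(df, values):
    return pd.Series(values, index=df["assessment_id"].to_numpy())


# -- build_pairs -------------------------------------------------------------

def test_latest_preadult_paired_with_adult():
    df = make_cohort([
        {"subject_id": "s1", "wave": 1, "age": 10.0, "risk": 1.0},
        {"subject_id": "s1", "wave": 2, "age": 14.0, "risk": 2.0},
        {"subject_id": "s1", "wave": 3, "age": 26.0, "risk": 0.0},
    ])
    dnam = dnam_series(df, [11.0, 15.0, 27.5])
    pairs = build_pairs(df, dnam, {"risk": "continuous"})
    assert len(pairs) == 1
    row = pairs.iloc[0]
    assert row["age_t2"] == 14.0 and row["age_t3"] == 26.0  # age-10 row dropped
    assert row["delta_dnam_age"] == pytest.approx(12.5)
    assert row["delta_age"] == pytest.approx(12.0)


def test_count_risk_uses_cumulative_exposure_at_t2():
    df = make_cohort([
        {"subject_id": "s1", "wave": 1, "age": 10.0, "risk": 2.0},
        {"subject_id": "s1", "wave": 2, "age": 14.0, "risk": 3.0},
        {"subject_id": "s1", "wave": 3, "age": 26.0, "risk": 1.0},
    ])
    dnam = dnam_series(df, [10.0, 14.0, 26.0])
    pairs = build_pairs(df, dnam, {"risk": "count"})
    assert pairs.iloc[0]["risk_t2"] == 5.0   # 2 + 3 across childhood waves
    assert pairs.iloc[0]["risk_t3"] == 6.0


def test_single_assessment_subjects_excluded():
    df = make_cohort([
        {"subject_id": "s1", "wave": 1, "age": 12.0, "risk": 1.0},
        {"subject_id": "s2", "wave": 1, "age": 25.0, "risk": 1.0},
        {"subject_id": "s3", "wave": 1, "age": 12.0, "risk": 1.0},
        {"subject_id": "s3", "wave": 2, "age": 24.0, "risk": 1.0},
    ])
    dnam = dnam_series(df, [12.0, 25.0, 12.0, 24.0])
    pairs = build_pairs(df, dnam, {"risk": "continuous"})
    assert list(pairs["subject_id"]) == ["s3"]


def test_earliest_adult_assessment_used():
    df = make_cohort([
        {"subject_id": "s1", "wave": 1, "age": 14.0, "risk": 1.0},
        {"subject_id": "s1", "wave": 2, "age": 19.0, "risk": 1.0},
        {"subject_id": "s1", "wave": 3, "age": 25.0, "risk": 1.0},
    ])
    dnam = dnam_series(df, [14.0, 19.0, 25.0])
    pairs = build_pairs(df, dnam, {"risk": "continuous"})
    assert pairs.iloc[0]["age_t3"] == 19.0


def test_complete_two_wave_cohort_keeps_every_subject():
    cfg = SimulationConfig(n_subjects=100, wave_probs=(0.0, 1.0, 0.0),
                           n_sites=0, n_age_sites=0, risks=(),
                           covariate_effects={}, seed=1)
    cohort, _, truth = generate_cohort(cfg)
    pairs = build_pairs(cohort, perfect_clock_dnam(cohort, truth), {})
    assert len(pairs) == 100


# -- fit_lagged --------------------------------------------------------------

def synth_pairs(n=300, b_months=2.0, noise=0.0, seed=0):
    """Pairs whose outcome is an exact linear function of the design."""
    rng = np.random.default_rng(seed)
    risk = rng.poisson(3.0, n).astype(float)
    delta_age = rng.uniform(8, 14, n)
    age_t3 = rng.uniform(18, 35, n)
    sex = rng.integers(0, 2, n).astype(float)
    outcome = (b_months / 12.0) * risk + 0.3 * delta_age - 0.05 * age_t3 \
        + 0.4 * sex + rng.normal(0, noise, n)
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "delta_dnam_age": outcome, "risk_t2": risk,
        "delta_age": delta_age, "age_t3": age_t3, "sex": sex,
        "race_ethnicity": "one_level",
    })


def test_noise_free_recovery_to_machine_precision():
    pairs = synth_pairs(b_months=1.67, noise=0.0)
    fit = LaggedChangeModel(pairs, "risk", "count").fit()
    assert fit.b == pytest.approx(1.67, abs=1e-9)
    assert fit.b == pytest.approx(12.0 * fit.b_raw)  # month/year round trip


def test_confidence_interval_is_wald():
    pairs = synth_pairs(noise=0.5, seed=1)
    fit = LaggedChangeModel(pairs, "risk", "count").fit()
    lo, hi = fit.ci95
    assert lo == pytest.approx(fit.b - 1.96 * fit.se, abs=0.01 * fit.se)
    assert hi == pytest.approx(fit.b + 1.96 * fit.se, abs=0.01 * fit.se)
    assert lo < fit.b < hi


def test_zero_variance_predictor_errors():
    pairs = synth_pairs(noise=0.1)
    pairs["risk_t2"] = 4.0
    with pytest.raises(ValueError, match="zero variance"):
        LaggedChangeModel(pairs, "risk", "count").fit()


def test_fully_adjusted_leaves_null_effect_unchanged():
    """Without mediation, adding lifestyle covariates should not move
    the focal coefficient beyond Monte-Carlo error."""
    cfg = SimulationConfig(n_subjects=380, wave_probs=(0.0, 1.0, 0.0),
                           n_sites=0, n_age_sites=0, seed=31)
    cohort, _, truth = generate_cohort(cfg)
    dnam = perfect_clock_dnam(cohort, truth)
    fam = {r.name: r.family for r in cfg.risks}
    pairs = build_pairs(cohort, dnam, fam)
    base = LaggedChangeModel(pairs, "depressive_symptoms", "count").fit()
    full = LaggedChangeModel(pairs, "depressive_symptoms", "count",
                             fully_adjusted=True).fit()
    assert full.b == pytest.approx(base.b, abs=2.0 * base.se)


def test_lagged_table_fdr_and_flagged_rows():
    pairs = synth_pairs(b_months=3.0, noise=0.3, seed=2)
    pairs["null_t2"] = np.random.default_rng(3).normal(size=len(pairs))
    pairs["flat_t2"] = 1.0
    fam = {"risk": "count", "null": "continuous", "flat": "continuous"}
    table = lagged_table(pairs, fam)
    assert set(table["risk"]) == {"risk", "null", "flat"}
    flat = table[table["risk"] == "flat"].iloc[0]
    assert "error" in flat["note"] and np.isnan(flat["p"])
    strong = table[table["risk"] == "risk"].iloc[0]
    assert strong["p_fdr"] < 0.01
    ok = table["p"].notna()
    assert (table.loc[ok, "p_fdr"] >= table.loc[ok, "p"] - 1e-12).all()


# -- reverse direction -------------------------------------------------------

def test_reverse_effect_recovered():
    cfg = SimulationConfig(
        n_subjects=1000, wave_probs=(0.0, 1.0, 0.0), n_sites=0, n_age_sites=0,
        risks=(RiskSpec("bmi", "continuous", mean=24.0, sd=4.0, icc=0.6),),
        covariate_effects={}, seed=41)
    cohort, _, truth = generate_cohort(cfg)
    dnam = perfect_clock_dnam(cohort, truth)
    aging = pd.Series(truth.deviation, index=cohort["assessment_id"].to_numpy())
    pairs = build_pairs(cohort, dnam, {"bmi": "continuous"}, aging=aging)
    c = 2.0  # risk units per year of pre-adult epigenetic aging
    pairs["delta_bmi"] = pairs["delta_bmi"] + c * pairs["aging_t2"]
    fit = LaggedChangeModel(pairs, "bmi", "continuous", reverse=True).fit()
    assert fit.direction == "reverse"
    assert fit.b == pytest.approx(c, rel=0.15)


def test_reverse_null_calibration():
    cfg = SimulationConfig(
        n_subjects=300, wave_probs=(0.0, 1.0, 0.0), n_sites=0, n_age_sites=0,
        risks=(RiskSpec("bmi", "continuous", mean=24.0, sd=4.0, icc=0.6),),
        covariate_effects={}, seed=0)
    rej = []
    for seed in range(200):
        cohort, _, truth = generate_cohort(cfg, seed=seed)
        dnam = perfect_clock_dnam(cohort, truth)
        aging = pd.Series(truth.deviation,
                          index=cohort["assessment_id"].to_numpy())
        pairs = build_pairs(cohort, dnam, {"bmi": "continuous"}, aging=aging)
        fit = LaggedChangeModel(pairs, "bmi", "continuous", reverse=True).fit()
        rej.append(fit.p < 0.05)
    # 95% binomial band around 0.05 at 200 replicates
    assert 0.02 <= np.mean(rej) <= 0.085


def test_reverse_requires_aging_column():
    pairs = synth_pairs()
    pairs["delta_risk"] = 1.0
    with pytest.raises(ValueError, match="aging_t2"):
        LaggedChangeModel(pairs, "risk", "count", reverse=True).fit()


# -- percentile effects ------------------------------------------------------

def test_flat_effect_gives_constant_percentile_predictions():
    # noise-free null: the risk coefficient is exactly zero, so every
    # percentile predicts the same change
    pairs = synth_pairs(b_months=0.0, noise=0.0, seed=5)
    fit = LaggedChangeModel(pairs, "risk", "count").fit()
    table = percentile_effects(fit)
    spread = table["predicted_change_months"].max() - table["predicted_change_months"].min()
    assert spread == pytest.approx(0.0, abs=1e-8)


def test_percentile_predictions_follow_slope_closed_form():
    pairs = synth_pairs(b_months=2.4, noise=0.0, seed=7)
    fit = LaggedChangeModel(pairs, "risk", "count").fit()
    table = percentile_effects(fit, percentiles=(10, 50, 90))
    q = table["predictor_value"].to_numpy()
    pred = table["predicted_change_months"].to_numpy()
    # differences between percentiles are exactly b * (q_p - q_p')
    assert pred[2] - pred[0] == pytest.approx(fit.b * (q[2] - q[0]), abs=1e-8)
    assert pred[1] - pred[0] == pytest.approx(fit.b * (q[1] - q[0]), abs=1e-8)


def test_median_prediction_near_outcome_mean():
    pairs = synth_pairs(b_months=1.2, noise=0.1, seed=8)
    fit = LaggedChangeModel(pairs, "risk", "count").fit()
    table = percentile_effects(fit, percentiles=(50,))
    # with covariates at their means and the predictor near its mean,
    # the prediction sits near the mean outcome
    assert table["predicted_change_months"].iloc[0] == pytest.approx(
        12.0 * pairs["delta_dnam_age"].mean(), abs=1.0)


def test_percentile_bounds_validated():
    pairs = synth_pairs(noise=0.1, seed=9)
    fit = LaggedChangeModel(pairs, "risk", "count").fit()
    with pytest.raises(ValueError):
        percentile_effects(fit, percentiles=(0, 50))
    with pytest.raises(ValueError):
        percentile_effects(fit, percentiles=(50, 100))
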