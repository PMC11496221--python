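"""Site ranking, nested cross-validation, and accuracy metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiaging import (MethylationClock, MethylationMatrix, compute_metrics,
                      rank_sites, traditional_r2)
from epiaging.clock import check_no_subject_leakage


def make_matrix(scores, prefix="s"):
    n_sites, n_cols = scores.shape
    return MethylationMatrix([f"{prefix}{i:03d}" for i in range(n_sites)],
                             [f"a{j:03d}" for j in range(n_cols)], scores)


# -- rank_sites --------------------------------------------------------------

def test_perfect_signal_site_ranks_first():
    rng = np.random.default_rng(0)
    ages = rng.uniform(9, 35, 200)
    scores = rng.normal(10, 1, size=(30, 200))
    scores[17] = 2.0 * ages / 4.0  # exactly linear in age
    order = rank_sites(scores, ages, [f"s{i:03d}" for i in range(30)])
    assert order[0] == 17


def test_rank_matches_per_site_ols_oracle():
    rng = np.random.default_rng(1)
    ages = rng.uniform(9, 35, 80)
    scores = rng.normal(10, 1, size=(25, 80))
    ids = [f"s{i:03d}" for i in range(25)]
    order = rank_sites(scores, ages, ids)
    # oracle: per-site OLS t statistics via linregress
    ts = np.array([abs(stats.linregress(ages, scores[i]).slope
                       / stats.linregress(ages, scores[i]).stderr)
                   for i in range(25)])
    expected = np.lexsort((ids, -ts))
    assert np.array_equal(order, expected)


def test_duplicate_site_gets_adjacent_ranks_in_id_order():
    rng = np.random.default_rng(2)
    ages = rng.uniform(9, 35, 60)
    scores = rng.normal(10, 1, size=(10, 60))
    scores[4] = scores[7].copy()  # duplicate signal under two IDs
    ids = [f"s{i:03d}" for i in range(10)]
    order = list(rank_sites(scores, ages, ids))
    pos4, pos7 = order.index(4), order.index(7)
    assert abs(pos4 - pos7) == 1 and pos4 < pos7


def test_constant_ages_error():
    with pytest.raises(ValueError, match="constant"):
        rank_sites(np.ones((3, 10)), np.full(10, 20.0), ["a", "b", "c"])


# -- metrics -----------------------------------------------------------------

def test_identity_prediction_metrics():
    ages = np.linspace(9, 35, 50)
    m = compute_metrics(ages, ages)
    assert m.mae == 0 and m.pearson_r == pytest.approx(1.0)
    assert m.r2 == pytest.approx(1.0) and m.mae_weighted == 0


def test_constant_shift_keeps_r_but_penalizes_r2():
    ages = np.linspace(9, 35, 50)
    m = compute_metrics(ages + 5.0, ages)
    assert m.pearson_r == pytest.approx(1.0)
    # identity-reference formula: R^2 = 1 - n*25 / SS_tot
    expected = 1.0 - 50 * 25.0 / ((ages - ages.mean()) ** 2).sum()
    assert m.r2 == pytest.approx(expected)
    assert m.r2 < 1.0


def test_weighted_mae_is_mae_over_age_range():
    ages = np.linspace(10, 30, 40)
    preds = ages + np.resize([2.0, -2.0], 40)
    m = compute_metrics(preds, ages)
    assert m.mae_weighted == pytest.approx(2.0 / 20.0)


def test_metrics_errors_on_degenerate_input():
    with pytest.raises(ValueError):
        compute_metrics(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        compute_metrics(np.array([1.0, 2.0, 3.0]), np.full(3, 5.0))


# -- cross-validation --------------------------------------------------------

def toy_cohort(n_subjects, rng, waves=1):
    rows = []
    for i in range(n_subjects):
        for w in range(waves):
            rows.append({"subject_id": f"S{i:03d}", "wave": w + 1,
                         "assessment_id": f"a{i * waves + w:03d}",
                         "age": rng.uniform(9, 35)})
    return pd.DataFrame(rows)


def test_single_linear_site_matches_fold_ols_oracle():
    """k=2, one perfectly age-linear site, lambda -> 0: the test-fold
    predictions equal the training fold's OLS line."""
    rng = np.random.default_rng(3)
    cohort = toy_cohort(8, rng)
    ages = cohort["age"].to_numpy()
    scores = (0.5 * ages)[None, :]
    meth = make_matrix(scores)
    clock = MethylationClock(meth, cohort, k=2, site_grid=[1], alphas=[1e-10])
    res = clock.fit(seed=0)
    pred = res.predictions
    for f in range(2):
        tr = pred["fold"] != f
        te = pred["fold"] == f
        slope, intercept, *_ = stats.linregress(scores[0, tr.to_numpy()],
                                                pred.loc[tr, "chronological_age"])
        oracle = intercept + slope * scores[0, te.to_numpy()]
        assert np.allclose(pred.loc[te, "dnam_age"], oracle, atol=1e-4)


def test_every_assessment_predicted_out_of_fold():
    rng = np.random.default_rng(4)
    cohort = toy_cohort(30, rng, waves=2)
    ages = cohort["age"].to_numpy()
    scores = np.vstack([0.3 * ages + rng.normal(0, 1, ages.size)
                        for _ in range(20)])
    res = MethylationClock(make_matrix(scores), cohort, k=5,
                           site_grid=[5, 10], alphas=[1.0, 10.0],
                           inner_k=3).fit(seed=0)
    pred = res.predictions
    assert pred["dnam_age"].notna().all()
    # folds partition subjects: both waves of a subject share a fold
    assert (pred.groupby("subject_id")["fold"].nunique() == 1).all()
    check_no_subject_leakage(pred["subject_id"].to_numpy(),
                             pred["fold"].to_numpy())


def test_subject_split_across_folds_detected():
    with pytest.raises(ValueError, match="split across folds"):
        check_no_subject_leakage(np.array(["a", "a", "b"]), np.array([0, 1, 1]))


def test_fold_assignment_deterministic_in_seed():
    rng = np.random.default_rng(5)
    cohort = toy_cohort(40, rng)
    ages = cohort["age"].to_numpy()
    scores = np.vstack([0.3 * ages + rng.normal(0, 1, ages.size)
                        for _ in range(10)])
    meth = make_matrix(scores)
    kw = dict(k=4, site_grid=[5], alphas=[1.0])
    r1 = MethylationClock(meth, cohort, **kw).fit(seed=9)
    r2 = MethylationClock(meth, cohort, **kw).fit(seed=9)
    r3 = MethylationClock(meth, cohort, **kw).fit(seed=10)
    assert np.array_equal(r1.predictions["fold"], r2.predictions["fold"])
    assert np.array_equal(r1.predictions["dnam_age"], r2.predictions["dnam_age"])
    assert not np.array_equal(r1.predictions["fold"], r3.predictions["fold"])


def test_site_grid_validation():
    rng = np.random.default_rng(6)
    cohort = toy_cohort(10, rng)
    scores = rng.normal(10, 1, (5, 10))
    with pytest.raises(ValueError, match="strictly increasing"):
        MethylationClock(make_matrix(scores), cohort, site_grid=[5, 5])
    with pytest.raises(ValueError, match="exceeds"):
        MethylationClock(make_matrix(scores), cohort, site_grid=[10])


def test_stopping_rule_terminates_and_reports_counts(default_sim, clock_results):
    grid = clock_results.site_grid
    for count in clock_results.chosen_site_counts:
        assert count in grid


def test_traditional_r2_constant_observed_errors():
    with pytest.raises(ValueError):
        traditional_r2(np.full(5, 3.0), np.arange(5.0))
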