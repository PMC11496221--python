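"""Cross-validated methylation-age clock.

Predicts chronological age from semi-quantitative methylation scores
with ridge regression, wrapped in k-fold cross-validation in which the
*entire* model-building cycle — per-site association ranking, stepwise
growth of the site count, and penalty selection — is repeated inside
each training fold.  Out-of-fold predictions are therefore unbiased:
no statistic computed on a test assessment (or any other assessment of
the same subject, since folds are formed at the subject level) ever
influences the model that predicts it.

The per-fold recipe:

1. rank all sites by the absolute t statistic of a per-site linear
   regression of score on age (a site-level association scan);
2. grow the number of top-ranked sites along ``site_grid``; at each
   count, pick the ridge penalty by inner subject-grouped
   cross-validation and record the inner-CV predictive power
   (bias-penalizing R^2);
3. stop when the power no longer improves by more than
   ``improvement_tol`` and keep the previous (smallest sufficient)
   count;
4. refit on the whole training fold and predict the held-out fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge

from .data import MethylationMatrix

DEFAULT_SITE_GRID = (50, 100, 200, 400, 800, 1600)
DEFAULT_ALPHAS = tuple(np.logspace(-2.0, 4.0, 7))


def rank_sites(scores: np.ndarray, ages: np.ndarray,
               site_ids: np.ndarray | list[str]) -> np.ndarray:
    """Order sites by strength of linear association with age.

    ``scores`` is sites x assessments (training columns only).  Returns
    site positions sorted by \\|t\\| of the per-site OLS slope,
    descending, ties broken by site ID so the order is deterministic.
    Zero-variance sites get t = 0.  Raises if ages are constant.
    """
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    if n < 3 or np.ptp(ages) == 0:
        raise ValueError("per-site association undefined: ages constant or too few")
    a = ages - ages.mean()
    s = scores - scores.mean(axis=1, keepdims=True)
    denom = np.sqrt((s ** 2).sum(axis=1) * (a ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, s @ a / denom, 0.0)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r ** 2)
    t = np.where(np.isfinite(t), t, np.sign(r) * np.inf)
    order = np.lexsort((np.asarray(site_ids), -np.abs(t)))
    return order


def _ridge_path(X_train, y_train, X_test, alphas):
    """Ridge predictions for every penalty at once via one SVD.

    Columns must already be standardized; the intercept is handled by
    centering y.  Matches ``sklearn.linear_model.Ridge`` solutions.
    """
    y_mean = y_train.mean()
    yc = y_train - y_mean
    U, s, Vt = np.linalg.svd(X_train, full_matrices=False)
    Uty = U.T @ yc
    alphas = np.asarray(alphas, dtype=float)
    # shrinkage factors per alpha: s / (s^2 + alpha)
    d = s[:, None] / (s[:, None] ** 2 + alphas[None, :])
    coefs = Vt.T @ (d * Uty[:, None])           # (p, n_alpha)
    return X_test @ coefs + y_mean


def traditional_r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    """R^2 against the identity prediction: 1 - SS(pred err)/SS(total).

    Unlike a squared correlation this penalizes systematic over- and
    under-estimation, so a clock that is perfectly correlated but
    biased scores below 1.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_tot = ((observed - observed.mean()) ** 2).sum()
    if ss_tot == 0:
        raise ValueError("R^2 undefined: observed values constant")
    return 1.0 - ((observed - predicted) ** 2).sum() / ss_tot


@dataclass
class ClockMetrics:
    """Out-of-fold accuracy summary of a clock."""
    mae: float              # years
    pearson_r: float
    r2: float               # bias-penalizing (identity-reference) R^2
    mae_weighted: float     # mae / chronological age range

    def as_dict(self) -> dict:
        return {"mae": self.mae, "pearson_r": self.pearson_r,
                "r2": self.r2, "mae_weighted": self.mae_weighted}


def compute_metrics(dnam_age: np.ndarray, chronological_age: np.ndarray) -> ClockMetrics:
    """Accuracy of predicted vs chronological age.

    ``mae_weighted`` normalizes the mean absolute error by the sample's
    chronological age range so clocks trained on cohorts with different
    age spans can be compared.
    """
    pred = np.asarray(dnam_age, dtype=float)
    obs = np.asarray(chronological_age, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 predictions")
    age_range = np.ptp(obs)
    if age_range == 0 or np.std(pred) == 0:
        raise ValueError("correlation undefined: constant ages or predictions")
    mae = float(np.mean(np.abs(pred - obs)))
    r = float(np.corrcoef(pred, obs)[0, 1])
    return ClockMetrics(mae=mae, pearson_r=r, r2=float(traditional_r2(obs, pred)),
                        mae_weighted=mae / float(age_range))


@dataclass
class FoldModel:
    """Ridge model trained on one outer training fold."""
    fold: int
    site_ids: list[str]
    n_sites: int
    alpha: float
    coef: np.ndarray = field(repr=False)
    intercept: float = 0.0
    feature_mean: np.ndarray = field(default=None, repr=False)
    feature_sd: np.ndarray = field(default=None, repr=False)
    inner_power: float = float("nan")

    def predict(self, scores: np.ndarray) -> np.ndarray:
        """Predict ages from a sites x assessments block matching
        ``site_ids`` row order."""
        X = (scores.T - self.feature_mean) / self.feature_sd
        return X @ self.coef + self.intercept


@dataclass
class ClockResults:
    """Out-of-fold predictions plus the per-fold models behind them."""
    predictions: pd.DataFrame   # assessment_id, subject_id, chronological_age, dnam_age, fold
    fold_models: list[FoldModel]
    k: int
    site_grid: tuple[int, ...]

    @property
    def metrics(self) -> ClockMetrics:
        return compute_metrics(self.predictions["dnam_age"],
                               self.predictions["chronological_age"])

    @property
    def dnam_age(self) -> pd.Series:
        return self.predictions.set_index("assessment_id")["dnam_age"]

    @property
    def chosen_site_counts(self) -> list[int]:
        return [fm.n_sites for fm in self.fold_models]

    def summary(self) -> str:
        m = self.metrics
        lines = [
            "Cross-validated methylation-age clock",
            "=" * 45,
            f"assessments: {len(self.predictions)}   folds: {self.k}",
            f"site grid: {list(self.site_grid)}",
            f"chosen site counts per fold: {self.chosen_site_counts}",
            f"MAE:          {m.mae:8.3f} years",
            f"MAE_weighted: {m.mae_weighted:8.3f}",
            f"Pearson r:    {m.pearson_r:8.3f}",
            f"R^2:          {m.r2:8.3f}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.predictions.to_csv(path, sep="\t", index=False)


def _subject_folds(subjects: np.ndarray, k: int, rng: np.random.Generator) -> dict:
    """Deterministically assign whole subjects to k folds."""
    unique = np.sort(np.unique(subjects))
    if len(unique) < 2 * k:
        raise ValueError(f"need at least {2 * k} subjects for {k} folds "
                         "with >= 2 subjects per fold")
    shuffled = rng.permutation(unique)
    assignment = {}
    for fold, chunk in enumerate(np.array_split(shuffled, k)):
        for s in chunk:
            assignment[s] = fold
    return assignment


def check_no_subject_leakage(subjects: np.ndarray, fold: np.ndarray) -> None:
    """Raise if any subject's assessments span more than one fold."""
    df = pd.DataFrame({"subject": subjects, "fold": fold})
    bad = df.groupby("subject")["fold"].nunique()
    bad = bad[bad > 1]
    if len(bad):
        raise ValueError(f"subjects split across folds: {list(bad.index[:5])}")


class MethylationClock:
    """Subject-grouped, nested cross-validated ridge age clock.

    Parameters
    ----------
    meth : MethylationMatrix
        Sites x assessments scores.
    cohort : DataFrame
        Must contain ``assessment_id``, ``subject_id`` and ``age``;
        joined to the matrix columns by assessment ID.
    k : int
        Outer folds (default 10).  Folds partition *subjects*, so all
        assessments of one subject share a fold.
    site_grid : increasing sequence of int
        Candidate numbers of top-ranked sites; grown stepwise until the
        inner-CV predictive power stops increasing.
    alphas : sequence of float
        Ridge penalty grid searched by inner cross-validation.
    inner_k : int
        Inner folds for penalty selection and the stopping rule.
    improvement_tol : float
        Minimum inner-CV R^2 gain required to accept a larger site count.
    """

    def __init__(self, meth: MethylationMatrix, cohort: pd.DataFrame, *,
                 k: int = 10, site_grid=None, alphas=DEFAULT_ALPHAS,
                 inner_k: int = 5, improvement_tol: float = 1e-3):
        if k < 2:
            raise ValueError("k must be >= 2")
        cohort = cohort.set_index("assessment_id").loc[meth.assessment_ids]
        self.meth = meth
        self.subjects = cohort["subject_id"].to_numpy()
        self.ages = cohort["age"].to_numpy(dtype=float)
        self.k = k
        if site_grid is None:
            site_grid = [g for g in DEFAULT_SITE_GRID if g <= meth.n_sites] or [meth.n_sites]
        site_grid = tuple(int(g) for g in site_grid)
        if any(b <= a for a, b in zip(site_grid, site_grid[1:])):
            raise ValueError("site_grid must be strictly increasing")
        if site_grid[-1] > meth.n_sites:
            raise ValueError("site_grid exceeds the number of sites")
        self.site_grid = site_grid
        self.alphas = tuple(float(a) for a in alphas)
        self.inner_k = inner_k
        self.improvement_tol = improvement_tol

    # -- internals ---------------------------------------------------------

    def _inner_power(self, X: np.ndarray, y: np.ndarray,
                     inner_assign: np.ndarray) -> tuple[float, float]:
        """Pooled inner-CV predictive power; returns (best R^2, best alpha)."""
        n_alpha = len(self.alphas)
        preds = np.empty((y.size, n_alpha))
        for f in range(self.inner_k):
            val = inner_assign == f
            tr = ~val
            mu = X[tr].mean(axis=0)
            sd = X[tr].std(axis=0)
            sd[sd == 0] = 1.0
            preds[val] = _ridge_path((X[tr] - mu) / sd, y[tr],
                                     (X[val] - mu) / sd, self.alphas)
        r2s = [traditional_r2(y, preds[:, j]) for j in range(n_alpha)]
        best = int(np.argmax(r2s))
        return r2s[best], self.alphas[best]

    def _fit_fold(self, fold: int, train: np.ndarray, test: np.ndarray,
                  rng: np.random.Generator) -> tuple[FoldModel, np.ndarray]:
        scores = self.meth.scores
        ages_tr = self.ages[train]
        order = rank_sites(scores[:, train], ages_tr,
                           np.asarray(self.meth.site_ids))

        if len(self.site_grid) == 1 and len(self.alphas) == 1:
            # nothing to select; no inner CV needed
            chosen = (self.site_grid[0], self.alphas[0], float("nan"))
        else:
            # inner folds partition training subjects
            subj_tr = self.subjects[train]
            inner_map = _subject_folds(subj_tr, self.inner_k, rng)
            inner_assign = np.array([inner_map[s] for s in subj_tr])

            chosen = None
            prev_power = -np.inf
            for m in self.site_grid:
                X = scores[order[:m]][:, train].T
                power, alpha = self._inner_power(X, ages_tr, inner_assign)
                if power <= prev_power + self.improvement_tol and chosen is not None:
                    break  # predictive power stopped increasing: keep previous count
                chosen = (m, alpha, power)
                prev_power = power

        m, alpha, power = chosen
        idx = order[:m]
        X_tr = scores[idx][:, train].T
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        sd[sd == 0] = 1.0
        model = Ridge(alpha=alpha)
        model.fit((X_tr - mu) / sd, ages_tr)
        fm = FoldModel(
            fold=fold, site_ids=[self.meth.site_ids[j] for j in idx],
            n_sites=m, alpha=alpha, coef=model.coef_.copy(),
            intercept=float(model.intercept_), feature_mean=mu, feature_sd=sd,
            inner_power=power)
        preds = fm.predict(scores[idx][:, test])
        return fm, preds

    # -- public API --------------------------------------------------------

    def fit(self, seed: int = 0) -> ClockResults:
        """Run the full nested cross-validation and return out-of-fold
        predictions for every assessment."""
        rng = np.random.default_rng(seed)
        fold_map = _subject_folds(self.subjects, self.k, rng)
        fold = np.array([fold_map[s] for s in self.subjects])
        check_no_subject_leakage(self.subjects, fold)

        dnam = np.full(self.ages.size, np.nan)
        models = []
        for f in range(self.k):
            test = np.flatnonzero(fold == f)
            train = np.flatnonzero(fold != f)
            fm, preds = self._fit_fold(f, train, test, rng)
            dnam[test] = preds
            models.append(fm)

        predictions = pd.DataFrame({
            "assessment_id": self.meth.assessment_ids,
            "subject_id": self.subjects,
            "chronological_age": self.ages,
            "dnam_age": dnam,
            "fold": fold,
        })
        return ClockResults(predictions=predictions, fold_models=models,
                            k=self.k, site_grid=self.site_grid)
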