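"""Lagged change-score models: childhood exposure -> adult epigenetic aging.

For each subject with at least one pre-adult (age < 17) and one adult
(age >= 17) methylation assessment, the latest pre-adult assessment
(T2) and the adult assessment (T3) form a pair.  T2 is chosen as the
*latest* pre-adult wave to capture the largest cumulative exposure
history; earlier pre-adult waves (T1) are dropped.  The forward model
is an OLS regression of the change in methylation-predicted age
(DNAm age at T3 minus at T2, in years) on the T2 risk exposure, always
adjusting for the change in chronological age and the adult age — so
the coefficient measures *epigenetic aging*, i.e. age-adjusted change —
plus sex, race/ethnicity, cell-proportion and technical covariates
(adult values and T3-T2 deltas).  Coefficients are reported in months
per risk unit (12 x the year-scale slope).

The reverse direction swaps the roles: pre-adult epigenetic aging
predicts the adult change in the risk, adjusting for the T2 risk value.

Count and binary exposures enter as their cumulative (rolling-sum)
value at T2; continuous exposures as the (mean-filled) observed T2
value, winsorized at 3 SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .preprocess import (_collinear_columns, bh_fdr, build_design,
                         fill_cohort_risk, winsorize)

logger = logging.getLogger(__name__)

ADULT_AGE = 17.0
BASE_COVARIATES = ("delta_age", "age_t3", "sex", "race_ethnicity")
DEFAULT_ADJUST_RISKS = ("bmi", "smoking", "cannabis", "alcohol")


def build_pairs(cohort: pd.DataFrame, dnam_age: pd.Series,
                families: dict[str, str], aging: pd.Series | None = None,
                adult_age: float = ADULT_AGE) -> pd.DataFrame:
    """Assemble (T2, T3) assessment pairs, one row per eligible subject.

    ``dnam_age`` (and optionally ``aging``, the residualized measure)
    are indexed by ``assessment_id``.  Subjects lacking a pre-adult or
    an adult assessment are excluded; a subject with several adult
    assessments contributes the earliest one (logged).  Count/binary
    risks are cumulated across waves before the T2 value is taken.
    """
    df = cohort.copy()
    df["_dnam"] = df["assessment_id"].map(dnam_age)
    if aging is not None:
        df["_aging"] = df["assessment_id"].map(aging)
    filled = {}
    for risk, fam in families.items():
        mode = "mean" if fam == "continuous" else "rolling_sum"
        filled[risk] = fill_cohort_risk(df, risk, mode)

    cell_tech = [c for c in ("cd3", "cd14", "cd15", "cd19", "tech1", "tech2")
                 if c in df.columns]
    ordered = df.sort_values(["subject_id", "age"], kind="stable")
    pre = ordered[ordered["age"] < adult_age]
    adult = ordered[ordered["age"] >= adult_age]
    n_multi = int((adult.groupby("subject_id").size() > 1).sum())
    if n_multi:
        logger.info("%d subjects have multiple adult assessments; "
                    "using the earliest for each", n_multi)
    t2 = pre.groupby("subject_id", sort=False).tail(1)
    t3 = adult.groupby("subject_id", sort=False).head(1)
    t2 = t2.set_index("subject_id")
    t3 = t3.set_index("subject_id")
    t2["_row"] = pre.groupby("subject_id", sort=False).tail(1).index
    t3["_row"] = adult.groupby("subject_id", sort=False).head(1).index
    common = t2.index.intersection(t3.index)
    t2, t3 = t2.loc[common], t3.loc[common]

    out = pd.DataFrame({
        "subject_id": common,
        "assessment_t2": t2["assessment_id"].to_numpy(),
        "assessment_t3": t3["assessment_id"].to_numpy(),
        "age_t2": t2["age"].to_numpy(), "age_t3": t3["age"].to_numpy(),
        "delta_age": t3["age"].to_numpy() - t2["age"].to_numpy(),
        "dnam_t2": t2["_dnam"].to_numpy(), "dnam_t3": t3["_dnam"].to_numpy(),
        "delta_dnam_age": t3["_dnam"].to_numpy() - t2["_dnam"].to_numpy(),
    })
    for col in ("sex", "race_ethnicity"):
        if col in t2.columns:
            out[col] = t2[col].to_numpy()
    if aging is not None:
        out["aging_t2"] = t2["_aging"].to_numpy()
        out["aging_t3"] = t3["_aging"].to_numpy()
    for c in cell_tech:
        out[f"{c}_t3"] = t3[c].to_numpy()
        out[f"delta_{c}"] = t3[c].to_numpy() - t2[c].to_numpy()
    for risk in families:
        v2 = filled[risk].loc[t2["_row"]].to_numpy()
        v3 = filled[risk].loc[t3["_row"]].to_numpy()
        out[f"{risk}_t2"] = v2
        out[f"{risk}_t3"] = v3
        out[f"delta_{risk}"] = v3 - v2
    return out


@dataclass
class LaggedResults:
    """One change-score regression (one table row)."""

    risk: str
    direction: str            # "forward" or "reverse"
    b: float                  # months/unit (forward); risk-units/year (reverse)
    se: float
    ci95: tuple[float, float]
    p: float
    n: int
    fully_adjusted: bool
    b_raw: float              # coefficient on the fitted (year) scale
    sm_results: object = field(repr=False, default=None)
    predictor_values: np.ndarray = field(repr=False, default=None)
    p_fdr: float = float("nan")

    def summary(self) -> str:
        unit = "months/unit" if self.direction == "forward" else "risk-units/year"
        return (f"{self.direction} lagged model for {self.risk} "
                f"({'fully adjusted' if self.fully_adjusted else 'base'}, n={self.n})\n"
                f"  b = {self.b:.3f} {unit}  SE = {self.se:.3f}  "
                f"95% CI [{self.ci95[0]:.3f}, {self.ci95[1]:.3f}]  p = {self.p:.4g}")


class LaggedChangeModel:
    """OLS change-score model for one risk.

    Parameters
    ----------
    pairs : DataFrame
        Output of :func:`build_pairs`.
    risk : str
        Focal risk name.
    family : str
        "count", "continuous" or "binary"; continuous predictors are
        winsorized at ``winsor_z`` SD before fitting.
    fully_adjusted : bool
        Additionally adjust for the adult values and T3-T2 deltas of
        ``adjust_risks`` (lifestyle confounders), mirroring a
        robustness model.
    reverse : bool
        Swap direction: pre-adult epigenetic aging predicts the change
        in the risk, adjusting for the T2 risk value (requires
        ``aging_t2`` in the pairs table).
    """

    def __init__(self, pairs: pd.DataFrame, risk: str, family: str = "count", *,
                 fully_adjusted: bool = False,
                 adjust_risks: tuple[str, ...] = DEFAULT_ADJUST_RISKS,
                 reverse: bool = False, winsor_z: float = 3.0):
        self.pairs = pairs
        self.risk = risk
        self.family = family
        self.fully_adjusted = fully_adjusted
        self.reverse = reverse
        self.adjust_risks = tuple(r for r in adjust_risks if r != risk)
        self.winsor_z = winsor_z

    def _design(self) -> tuple[pd.Series, pd.DataFrame, str]:
        pairs = self.pairs
        predictor_col = f"{self.risk}_t2"
        x = pairs[predictor_col].astype(float)
        if self.family == "continuous":
            x = pd.Series(winsorize(x, self.winsor_z), index=pairs.index,
                          name=predictor_col)
        if self.reverse:
            if "aging_t2" not in pairs.columns:
                raise ValueError("reverse models need aging_t2 in the pairs table "
                                 "(pass aging= to build_pairs)")
            y = pairs[f"delta_{self.risk}"].astype(float)
            cov_cols = {"aging_t2": pairs["aging_t2"], predictor_col: x}
            predictor = "aging_t2"
        else:
            y = pairs["delta_dnam_age"].astype(float)
            cov_cols = {predictor_col: x}
            predictor = predictor_col
        # cd15 (granulocytes) is the reference cell type: the four
        # proportions sum to one, and the four deltas to zero
        for c in BASE_COVARIATES:
            cov_cols[c] = pairs[c]
        for c in pairs.columns:
            if c.endswith("_t3") and c[:-3] in ("cd3", "cd14", "cd19",
                                                "tech1", "tech2"):
                cov_cols[c] = pairs[c]
                cov_cols[f"delta_{c[:-3]}"] = pairs[f"delta_{c[:-3]}"]
        if self.fully_adjusted and not self.reverse:
            for r in self.adjust_risks:
                if f"{r}_t3" in pairs.columns:
                    cov_cols[f"{r}_t3"] = pairs[f"{r}_t3"]
                    cov_cols[f"delta_{r}"] = pairs[f"delta_{r}"]
        design = pd.DataFrame(cov_cols)
        return y, design, predictor

    def fit(self) -> LaggedResults:
        y, design, predictor = self._design()
        if design[predictor].std() == 0:
            raise ValueError(f"predictor {predictor!r} has zero variance")
        if y.std() == 0:
            raise ValueError("outcome has zero variance")
        X = build_design(design)
        Xm = X.to_numpy(dtype=float)
        if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
            bad = _collinear_columns(Xm, list(X.columns))
            raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")
        res = sm.OLS(y.to_numpy(dtype=float), Xm).fit()
        idx = list(X.columns).index(predictor)
        scale = 12.0 if not self.reverse else 1.0
        b_raw = float(res.params[idx])
        se = float(res.bse[idx])
        ci = res.conf_int()[idx]
        result = LaggedResults(
            risk=self.risk,
            direction="reverse" if self.reverse else "forward",
            b=scale * b_raw, se=scale * se,
            ci95=(scale * float(ci[0]), scale * float(ci[1])),
            p=float(res.pvalues[idx]), n=int(res.nobs),
            fully_adjusted=self.fully_adjusted, b_raw=b_raw,
            sm_results=res,
            predictor_values=design[predictor].to_numpy(dtype=float))
        result._exog_columns = list(X.columns)
        result._exog_mean = Xm.mean(axis=0)
        result._predictor_index = idx
        return result


def lagged_table(pairs: pd.DataFrame, families: dict[str, str], *,
                 fully_adjusted: bool = False, reverse: bool = False,
                 adjust_risks: tuple[str, ...] = DEFAULT_ADJUST_RISKS) -> pd.DataFrame:
    """One change-score model per risk, FDR-corrected within the table.

    Forward and reverse tables are separate FDR families.  Per-risk
    failures (e.g. zero-variance predictors) become flagged rows.
    """
    rows, fits = [], {}
    for risk, fam in families.items():
        try:
            fit = LaggedChangeModel(pairs, risk, fam, fully_adjusted=fully_adjusted,
                                    reverse=reverse, adjust_risks=adjust_risks).fit()
            fits[risk] = fit
            rows.append({"risk": risk, "family": fam, "b": fit.b, "se": fit.se,
                         "ci_low": fit.ci95[0], "ci_high": fit.ci95[1],
                         "p": fit.p, "n": fit.n, "note": ""})
        except ValueError as exc:
            rows.append({"risk": risk, "family": fam, "b": np.nan, "se": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                         "n": 0, "note": f"error: {exc}"})
    table = pd.DataFrame(rows)
    adj = np.full(len(table), np.nan)
    ok = table["p"].notna().to_numpy()
    if ok.any():
        adj[ok] = bh_fdr(table.loc[ok, "p"].to_numpy())
    table["p_fdr"] = adj
    for risk, fit in fits.items():
        fit.p_fdr = float(table.loc[table["risk"] == risk, "p_fdr"].iloc[0])
    table.attrs["fits"] = fits
    return table


def percentile_effects(result: LaggedResults,
                       percentiles=(1, 5, 25, 50, 75, 95, 99)) -> pd.DataFrame:
    """Model-predicted epigenetic-aging change (months) at percentiles
    of the observed predictor distribution, other covariates at their
    sample means.

    ``predicted_change_months`` is the absolute predicted change, which
    over a decade-long follow-up is dominated by ordinary chronological
    aging; ``relative_change_months`` subtracts the prediction at the
    mean predictor value, i.e. how much older or younger than the
    cohort's expectation a person at that percentile is predicted to
    end up.
    """
    percentiles = np.asarray(percentiles, dtype=float)
    if np.any((percentiles <= 0) | (percentiles >= 100)):
        raise ValueError("percentiles must lie strictly between 0 and 100")
    qs = np.percentile(result.predictor_values, percentiles)
    x_row = result._exog_mean.copy()
    reference = float(result.sm_results.predict(x_row[None, :])[0])
    preds = []
    for q in qs:
        x_row[result._predictor_index] = q
        preds.append(float(result.sm_results.predict(x_row[None, :])[0]))
    scale = 12.0 if result.direction == "forward" else 1.0
    preds = np.asarray(preds)
    return pd.DataFrame({
        "percentile": percentiles,
        "predictor_value": qs,
        "predicted_change_months": scale * preds,
        "relative_change_months": scale * (preds - reference),
    })


def plot_percentile_effects(result: LaggedResults,
                            percentiles=(1, 5, 10, 25, 50, 75, 90, 95, 99),
                            path=None):
    """Percentile-vs-predicted-change figure for one lagged model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = percentile_effects(result, percentiles)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(table["percentile"], table["predicted_change_months"],
            marker="o", color="#2c5f8a")
    ax.axhline(0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel(f"{result.risk} percentile")
    ax.set_ylabel("predicted change in epigenetic aging (months)")
    ax.set_title(f"Lagged effect of {result.risk}"
                 + (" (fully adjusted)" if result.fully_adjusted else ""))
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
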