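"""Analysis-ready derived quantities.

Covers the four preprocessing devices of the pipeline: residualizing raw
methylation-predicted age on chronological age and covariates (the
residual is the *epigenetic aging* measure), z-score winsorization of
continuous variables, rolling-sum / mean handling of missing wave
responses, and Benjamini-Hochberg FDR adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests


def build_design(design: pd.DataFrame, *, age_col: str | None = None,
                 quadratic_age: bool = False, add_intercept: bool = True) -> pd.DataFrame:
    """Encode a covariate table into a numeric design matrix.

    Categorical (object / category / boolean) columns become one-hot
    dummies with the first level as reference; numeric columns pass
    through.  With ``quadratic_age`` the square of ``age_col`` is
    appended, so age is adjusted with both linear and quadratic terms.
    """
    parts = []
    if add_intercept:
        parts.append(pd.Series(1.0, index=design.index, name="intercept"))
    for col in design.columns:
        s = design[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        else:
            parts.append(s.astype(float))
    X = pd.concat(parts, axis=1)
    if quadratic_age:
        if age_col is None or age_col not in design.columns:
            raise ValueError("quadratic_age requires age_col present in the design")
        X[f"{age_col}_sq"] = design[age_col].astype(float) ** 2
    return X


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name the columns a pivoted QR marks as linearly dependent."""
    from scipy.linalg import qr
    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def residualize(values: np.ndarray | pd.Series, design: pd.DataFrame, *,
                age_col: str | None = None, quadratic_age: bool = False) -> np.ndarray:
    """OLS residuals of ``values`` on an encoded covariate design.

    Used to turn raw methylation-predicted age into epigenetic aging:
    residualizing on chronological age (optionally with a quadratic
    term) while the other covariates share the fit, so their variance
    shared with age is accounted for rather than left in the residual.

    Raises ``ValueError`` naming the offending columns if the encoded
    design is rank deficient.
    """
    y = np.asarray(values, dtype=float)
    X = build_design(design, age_col=age_col, quadratic_age=quadratic_age)
    if y.shape[0] != X.shape[0]:
        raise ValueError("values and design have different lengths")
    Xm = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        bad = _collinear_columns(Xm, list(X.columns))
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    return y - Xm @ beta


def winsorize(values: np.ndarray | pd.Series, z: float = 3.0) -> np.ndarray:
    """Clamp values beyond ``mean +/- z * sd`` back to that threshold.

    Mean and SD are those of the input, computed once before clamping.
    Zero-variance input is returned unchanged.
    """
    v = np.asarray(values, dtype=float)
    finite = v[np.isfinite(v)]
    if finite.size < 2:
        raise ValueError("winsorize needs at least 2 finite values")
    mu, sd = finite.mean(), finite.std(ddof=1)
    if sd == 0:
        return v.copy()
    return np.clip(v, mu - z * sd, mu + z * sd)


def fill_waves(values: np.ndarray | pd.Series, mode: str) -> np.ndarray:
    """Fill one subject's wave series (ordered in time, NaN = missing).

    ``rolling_sum`` returns the cumulative sum across waves with missing
    waves contributing zero — a cumulative-exposure score appropriate
    for risks where absence of a report means absence of the exposure.
    ``mean`` leaves observed waves untouched and substitutes the
    subject's mean of observed waves for missing ones — appropriate for
    variables that cannot be zero (e.g. BMI).
    """
    v = np.asarray(values, dtype=float)
    observed = np.isfinite(v)
    if not observed.any():
        raise ValueError("subject has no observed waves")
    if mode == "rolling_sum":
        return np.cumsum(np.where(observed, v, 0.0))
    if mode == "mean":
        out = v.copy()
        out[~observed] = v[observed].mean()
        return out
    raise ValueError(f"unknown fill mode {mode!r}")


def fill_cohort_risk(cohort: pd.DataFrame, risk: str, mode: str,
                     subject_col: str = "subject_id",
                     wave_col: str = "wave") -> pd.Series:
    """Apply the :func:`fill_waves` rule per subject to one risk column
    of a long-format cohort table; returns a series aligned with the
    input rows."""
    if mode not in ("rolling_sum", "mean"):
        raise ValueError(f"unknown fill mode {mode!r}")
    df = cohort.sort_values([subject_col, wave_col], kind="stable")
    v = df[risk].astype(float)
    groups = df[subject_col]
    observed_per_subject = v.notna().groupby(groups).transform("sum")
    if (observed_per_subject == 0).any():
        bad = groups[observed_per_subject == 0].iloc[0]
        raise ValueError(f"subject {bad!r} has no observed waves for {risk!r}")
    if mode == "rolling_sum":
        out = v.fillna(0.0).groupby(groups).cumsum()
    else:
        out = v.fillna(v.groupby(groups).transform("mean"))
    out.name = risk
    return out.loc[cohort.index]


#: covariates adjusted for in concurrent analyses (with a quadratic age
#: term added on top): demographics, pubertal stage, estimated blood
#: cell-type proportions and lab technical covariates.  The granulocyte
#: fraction (cd15) is the reference cell type: the four proportions sum
#: to one, so entering all four alongside an intercept would be
#: collinear.
CONCURRENT_COVARIATES = ("age", "sex", "tanner", "race_ethnicity",
                         "cd3", "cd14", "cd19", "tech1", "tech2")


def epigenetic_aging(cohort: pd.DataFrame, dnam_age: pd.Series,
                     covariate_cols=CONCURRENT_COVARIATES, *,
                     quadratic_age: bool = True) -> pd.Series:
    """Residualize raw methylation-predicted age into epigenetic aging.

    ``dnam_age`` is indexed by ``assessment_id``.  Returns the residual
    series (years), indexed by ``assessment_id``; positive values mean
    biologically older than expected for chronological age.
    """
    cols = [c for c in covariate_cols if c in cohort.columns]
    values = cohort["assessment_id"].map(dnam_age)
    resid = residualize(values.to_numpy(dtype=float), cohort[cols],
                        age_col="age", quadratic_age=quadratic_age)
    return pd.Series(resid, index=cohort["assessment_id"].to_numpy(),
                     name="epigenetic_aging")


def infer_family(values: pd.Series) -> str:
    """Heuristic risk family: binary (0/1), count (non-negative
    integers) or continuous.  Library callers should state families
    explicitly; this backs the command-line default."""
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    uniq = np.unique(v)
    if np.all(np.isin(uniq, (0.0, 1.0))):
        return "binary"
    if np.all(v >= 0) and np.allclose(v, np.rint(v)):
        return "count"
    return "continuous"


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
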