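"""Bivariate mixed model for subject/wave covariance decomposition.

Two responses — the epigenetic-aging residual and one health risk —
are measured repeatedly on the same subjects.  Their total covariance
is decomposed into a *subject-level* (between-person) part, carried by
stable differences among individuals, and a *wave-level*
(within-person) part, carried by co-occurring changes over time.

Model.  For subject ``i`` with ``n_i`` waves, stack the two responses
wave by wave into a ``2 n_i`` vector::

    y_i = X_i beta + Z_i u_i + e_i,   u_i ~ N(0, G),   e_ij ~ N(0, R)

with ``G`` and ``R`` unstructured 2x2 covariance matrices (random
subject intercepts for both responses; wave residuals independent
across waves), giving the marginal covariance
``V_i = I_{n_i} (x) R + J_{n_i} (x) G``.  Fixed effects are
response-specific: each covariate gets its own slope per response.

Estimation is maximum likelihood (REML optional).  ``G`` and ``R`` are
parameterized through Cholesky factors with log-diagonals, which keeps
them positive definite; ``beta`` is profiled out by generalized least
squares at every likelihood evaluation.  The total covariance is
``T = G + R`` by construction, and standardized contributions

    r_subject = G12 / sqrt(T11 T22),   r_wave = R12 / sqrt(T11 T22)

add up exactly to the total correlation ``r_total = T12 / sqrt(T11
T22)``.  The intra-class correlations ``G11 / T11`` and ``G22 / T22``
measure the temporal stability of each response.

Significance of either contribution is assessed by a likelihood-ratio
test against the model refit with the corresponding cross-covariance
pinned to zero (1 df); Wald tests are avoided because covariance
parameters near the boundary make them unreliable.  A significant
wave-level contribution is necessary but not sufficient evidence of a
causal effect; this module only reports the decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import optimize, stats

from .preprocess import bh_fdr, build_design, fill_cohort_risk, winsorize

_LOG2PI = np.log(2.0 * np.pi)
BOUNDARY_CORR = 0.995


def _chol_from_theta(t3: np.ndarray) -> np.ndarray:
    """(log l11, l21, log l22) -> 2x2 covariance L L'."""
    L = np.array([[np.exp(t3[0]), 0.0], [t3[1], np.exp(t3[2])]])
    return L @ L.T


def _theta_from_cov(M: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(M)
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _make_psd(M: np.ndarray, floor_frac: float = 1e-4) -> np.ndarray:
    """Eigen-clip a symmetric 2x2 to be safely positive definite."""
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    floor = max(floor_frac * max(np.trace(M), 1e-8), 1e-8)
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T


class ConvergenceError(RuntimeError):
    pass


@dataclass
class BivariateMixedResults:
    """Fitted covariance decomposition for one (aging, risk) pair."""

    model: "BivariateMixedModel"
    sigma_subject: np.ndarray      # G, 2x2
    sigma_wave: np.ndarray         # R, 2x2
    beta: pd.Series
    loglik: float
    converged: bool
    n_iter: int
    reml: bool
    start_loglik: float
    constrained: str | None = None

    @property
    def sigma_total(self) -> np.ndarray:
        return self.sigma_subject + self.sigma_wave

    # -- standardized quantities ------------------------------------------

    @property
    def r_total(self) -> float:
        T = self.sigma_total
        return float(T[0, 1] / np.sqrt(T[0, 0] * T[1, 1]))

    @property
    def r_subject(self) -> float:
        """Subject-level contribution, standardized by total variances."""
        T = self.sigma_total
        return float(self.sigma_subject[0, 1] / np.sqrt(T[0, 0] * T[1, 1]))

    @property
    def r_wave(self) -> float:
        """Wave-level contribution, standardized by total variances."""
        T = self.sigma_total
        return float(self.sigma_wave[0, 1] / np.sqrt(T[0, 0] * T[1, 1]))

    @property
    def corr_subject(self) -> float:
        """Correlation of the subject-level components (G-scale)."""
        G = self.sigma_subject
        return float(G[0, 1] / np.sqrt(G[0, 0] * G[1, 1]))

    @property
    def corr_wave(self) -> float:
        R = self.sigma_wave
        return float(R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]))

    @property
    def icc_y1(self) -> float:
        return float(self.sigma_subject[0, 0] / self.sigma_total[0, 0])

    @property
    def icc_y2(self) -> float:
        return float(self.sigma_subject[1, 1] / self.sigma_total[1, 1])

    @property
    def boundary(self) -> bool:
        """True when either component correlation sits at +/-1."""
        return (abs(self.corr_subject) > BOUNDARY_CORR
                or abs(self.corr_wave) > BOUNDARY_CORR)

    # -- tests -------------------------------------------------------------

    def lrt(self, level: str, boundary_mixture: bool = False) -> dict:
        """Likelihood-ratio test of a zero cross-covariance.

        ``level`` is ``"subject"`` (G12 = 0) or ``"wave"`` (R12 = 0).
        1-df chi-square by default; ``boundary_mixture`` halves the
        p-value (50:50 mixture), appropriate only for variance-like
        boundaries, hence off by default for a covariance.
        """
        if self.constrained is not None:
            raise ValueError("LRT must start from the unconstrained fit")
        if not self.converged:
            raise ConvergenceError("unconstrained fit did not converge")
        null = self.model.fit(constrain=level, start_from=self)
        if not null.converged:
            return {"stat": np.nan, "p": np.nan, "null_loglik": null.loglik,
                    "converged": False}
        stat = max(2.0 * (self.loglik - null.loglik), 0.0)
        p = float(stats.chi2.sf(stat, df=1))
        if boundary_mixture:
            p *= 0.5
        return {"stat": float(stat), "p": p, "null_loglik": null.loglik,
                "converged": True}

    def summary(self) -> str:
        G, R, T = self.sigma_subject, self.sigma_wave, self.sigma_total
        lines = [
            "Bivariate mixed model: covariance decomposition",
            "=" * 52,
            f"subjects: {self.model.n_subjects}   rows: {self.model.n_rows}"
            f"   {'REML' if self.reml else 'ML'}"
            f"   loglik: {self.loglik:.3f}   converged: {self.converged}",
            "",
            "               y1 (aging)    y2 (risk)",
            f"ICC            {self.icc_y1:10.3f}   {self.icc_y2:10.3f}",
            "",
            f"G (subject): [[{G[0,0]:.4f}, {G[0,1]:.4f}], [{G[1,0]:.4f}, {G[1,1]:.4f}]]",
            f"R (wave):    [[{R[0,0]:.4f}, {R[0,1]:.4f}], [{R[1,0]:.4f}, {R[1,1]:.4f}]]",
            f"T = G + R:   [[{T[0,0]:.4f}, {T[0,1]:.4f}], [{T[1,0]:.4f}, {T[1,1]:.4f}]]",
            "",
            f"r_total   = {self.r_total:7.4f}",
            f"r_subject = {self.r_subject:7.4f}   (contribution)",
            f"r_wave    = {self.r_wave:7.4f}   (contribution)",
        ]
        if self.boundary:
            lines.append("WARNING: boundary estimate (|component correlation| -> 1)")
        return "\n".join(lines)


class BivariateMixedModel:
    """Two-response linear mixed model with subject random intercepts.

    Parameters
    ----------
    y1, y2 : 1-d arrays
        The two responses, one value each per subject x wave row;
        rows with a missing value in either response are dropped
        (complete pairs).
    subjects : 1-d array
        Subject identifier per row.
    covariates : DataFrame, optional
        Per-row fixed-effect covariates; encoded via
        :func:`epiaging.preprocess.build_design` and entered with
        response-specific slopes.  An intercept per response is always
        included.
    reml : bool
        Restricted maximum likelihood instead of ML.
    """

    def __init__(self, y1, y2, subjects, covariates: pd.DataFrame | None = None,
                 *, reml: bool = False, quadratic_age: bool = False,
                 age_col: str = "age"):
        y1 = np.asarray(y1, dtype=float)
        y2 = np.asarray(y2, dtype=float)
        subjects = np.asarray(subjects)
        keep = np.isfinite(y1) & np.isfinite(y2)
        y1, y2, subjects = y1[keep], y2[keep], subjects[keep]
        if covariates is not None:
            covariates = covariates.loc[np.asarray(keep)].reset_index(drop=True)
            C = build_design(covariates, age_col=age_col,
                             quadratic_age=quadratic_age).to_numpy(dtype=float)
            self.cov_names = list(build_design(
                covariates, age_col=age_col, quadratic_age=quadratic_age).columns)
        else:
            C = np.ones((y1.size, 1))
            self.cov_names = ["intercept"]
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")

        self.n_rows = y1.size
        uniq, inv = np.unique(subjects, return_inverse=True)
        self.n_subjects = uniq.size
        if self.n_subjects < 30:
            raise ValueError("need >= 30 subjects to fit the bivariate model")
        counts = np.bincount(inv)
        if counts.max() < 2:
            raise ValueError("need subjects with >= 2 waves to separate "
                             "subject- from wave-level covariance")
        self.reml = reml
        q = C.shape[1]
        self.p = 2 * q

        # group subjects by wave count; build stacked (m, 2n) responses and
        # (m, 2n, p) designs with per-wave interleaving (y1, y2, y1, y2, ...)
        self._groups = []
        order = np.argsort(inv, kind="stable")
        row_of = np.split(order, np.cumsum(counts)[:-1])
        for n in np.unique(counts):
            subj_ids = np.flatnonzero(counts == n)
            m = subj_ids.size
            Y = np.empty((m, 2 * n))
            X = np.zeros((m, 2 * n, self.p))
            for a, s in enumerate(subj_ids):
                rows = row_of[s]
                Y[a, 0::2] = y1[rows]
                Y[a, 1::2] = y2[rows]
                X[a, 0::2, :q] = C[rows]
                X[a, 1::2, q:] = C[rows]
            self._groups.append((int(n), Y, X))
        self._y1, self._y2, self._inv, self._counts = y1, y2, inv, counts

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, y1: str, y2: str,
                       groups: str = "subject_id",
                       covariates: list[str] | None = None, **kwargs):
        cov = df[covariates].reset_index(drop=True) if covariates else None
        return cls(df[y1].to_numpy(), df[y2].to_numpy(),
                   df[groups].to_numpy(), cov, **kwargs)

    # -- likelihood --------------------------------------------------------

    def _theta_split(self, theta, constrain):
        t = np.asarray(theta, dtype=float)
        if constrain == "subject":
            g = np.array([t[0], 0.0, t[1]])
            r = t[2:5]
        elif constrain == "wave":
            g = t[0:3]
            r = np.array([t[3], 0.0, t[4]])
        else:
            g, r = t[0:3], t[3:6]
        return g, r

    def profiled_nll(self, theta, constrain=None):
        """Negative (RE)ML log-likelihood with beta profiled out by GLS."""
        g, r = self._theta_split(theta, constrain)
        G = _chol_from_theta(g)
        R = _chol_from_theta(r)
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        yVy = 0.0
        logdet = 0.0
        n_obs = 0
        for n, Y, X in self._groups:
            V = np.kron(np.eye(n), R) + np.kron(np.ones((n, n)), G)
            sign, ld = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e12
            Vinv = np.linalg.inv(V)
            m = Y.shape[0]
            logdet += m * ld
            n_obs += m * 2 * n
            YW = Y @ Vinv
            yVy += float(np.einsum("ma,ma->", YW, Y))
            XW = np.einsum("map,ab->mbp", X, Vinv)
            A += np.einsum("mbp,mbq->pq", XW, X)
            b += np.einsum("mbp,mb->p", XW, Y)
        try:
            cf = sla.cho_factor(A)
        except (sla.LinAlgError, ValueError):
            return 1e12
        beta = sla.cho_solve(cf, b)
        quad = yVy - b @ beta
        nll = 0.5 * (n_obs * _LOG2PI + logdet + quad)
        if self.reml:
            # + 0.5 log|X' V^-1 X| from the Cholesky factor of A
            nll += float(np.sum(np.log(np.diag(cf[0]))))
        return float(nll)

    def _gls_beta(self, G, R):
        A = np.zeros((self.p, self.p))
        b = np.zeros(self.p)
        for n, Y, X in self._groups:
            V = np.kron(np.eye(n), R) + np.kron(np.ones((n, n)), G)
            Vinv = np.linalg.inv(V)
            XW = np.einsum("map,ab->mbp", X, Vinv)
            A += np.einsum("mbp,mbq->pq", XW, X)
            b += np.einsum("mbp,mb->p", XW, Y)
        return np.linalg.solve(A, b)

    def moment_start(self):
        """ANOVA-type moment estimates of (G, R) used as starting values.

        Responses are first residualized on the fixed-effect design by
        OLS; the pooled within-subject SSCP gives R, and the covariance
        of subject means minus R over the harmonic-mean wave count
        gives G.
        """
        q = self.p // 2
        # reconstruct per-row residuals from the stacked design
        Cs, y1s, y2s, subj = [], [], [], []
        for n, Y, X in self._groups:
            m = Y.shape[0]
            for a in range(m):
                Cs.append(X[a, 0::2, :q])
                y1s.append(Y[a, 0::2])
                y2s.append(Y[a, 1::2])
                subj.append(np.full(n, len(subj)))
        C = np.vstack(Cs)
        y1 = np.concatenate(y1s)
        y2 = np.concatenate(y2s)
        subj = np.concatenate(subj)
        r1 = y1 - C @ np.linalg.lstsq(C, y1, rcond=None)[0]
        r2 = y2 - C @ np.linalg.lstsq(C, y2, rcond=None)[0]
        resid = np.column_stack([r1, r2])

        counts = np.bincount(subj)
        means = np.zeros((counts.size, 2))
        np.add.at(means, subj, resid)
        means /= counts[:, None]
        dev = resid - means[subj]
        dof_w = max(int((counts - 1).sum()), 1)
        S_w = dev.T @ dev / dof_w
        B = np.cov(means.T, ddof=1) if counts.size > 1 else np.eye(2)
        n_h = counts.size / np.sum(1.0 / counts)
        G0 = _make_psd(np.atleast_2d(B) - S_w / n_h)
        R0 = _make_psd(S_w)
        return G0, R0

    # -- fitting -----------------------------------------------------------

    def fit(self, *, constrain: str | None = None, start: tuple | None = None,
            start_from: BivariateMixedResults | None = None,
            maxiter: int = 500, tol: float = 1e-10) -> BivariateMixedResults:
        """Maximize the (restricted) likelihood.

        ``constrain`` pins one cross-covariance to zero ("subject" for
        G12, "wave" for R12) for likelihood-ratio testing.
        """
        if constrain not in (None, "subject", "wave"):
            raise ValueError("constrain must be None, 'subject' or 'wave'")
        if start_from is not None:
            G0 = start_from.sigma_subject.copy()
            R0 = start_from.sigma_wave.copy()
            if constrain == "subject":
                G0[0, 1] = G0[1, 0] = 0.0
            if constrain == "wave":
                R0[0, 1] = R0[1, 0] = 0.0
            G0, R0 = _make_psd(G0), _make_psd(R0)
        elif start is not None:
            G0, R0 = (_make_psd(np.asarray(m, dtype=float)) for m in start)
        else:
            G0, R0 = self.moment_start()
        g0 = _theta_from_cov(G0)
        r0 = _theta_from_cov(R0)
        if constrain == "subject":
            theta0 = np.array([g0[0], g0[2], r0[0], r0[1], r0[2]])
        elif constrain == "wave":
            theta0 = np.array([g0[0], g0[1], g0[2], r0[0], r0[2]])
        else:
            theta0 = np.concatenate([g0, r0])

        start_ll = -self.profiled_nll(theta0, constrain)
        bounds = [(-10.0, 10.0) if i in self._logdiag_idx(constrain)
                  else (-1e3, 1e3) for i in range(theta0.size)]
        res = optimize.minimize(
            self.profiled_nll, theta0, args=(constrain,), method="L-BFGS-B",
            bounds=bounds, options={"maxiter": maxiter, "ftol": tol,
                                    "gtol": 1e-8, "maxfun": 20000})
        g, r = self._theta_split(res.x, constrain)
        G = _chol_from_theta(g)
        R = _chol_from_theta(r)
        beta = self._gls_beta(G, R)
        names = ([f"y1:{c}" for c in self.cov_names]
                 + [f"y2:{c}" for c in self.cov_names])
        loglik = -float(res.fun)
        converged = bool(res.success) or res.status == 0
        return BivariateMixedResults(
            model=self, sigma_subject=G, sigma_wave=R,
            beta=pd.Series(beta, index=names), loglik=loglik,
            converged=converged, n_iter=int(res.nit), reml=self.reml,
            start_loglik=float(start_ll), constrained=constrain)

    @staticmethod
    def _logdiag_idx(constrain):
        if constrain == "subject":
            return {0, 1, 2, 4}
        if constrain == "wave":
            return {0, 2, 3, 4}
        return {0, 2, 3, 5}


def decomposition_table(cohort: pd.DataFrame, aging: pd.Series,
                        risks: list[str], families: dict[str, str],
                        covariate_cols: list[str] | None = None, *,
                        winsor_z: float = 3.0, reml: bool = False,
                        quadratic_age: bool = False) -> pd.DataFrame:
    """Covariance decompositions for a battery of risks, FDR-corrected.

    For each risk: missing waves are handled by the family rule
    (cumulative rolling sum for count/binary exposures, subject mean for
    continuous variables), continuous risks are winsorized at
    ``winsor_z`` SDs, the bivariate model is fitted jointly with the
    epigenetic-aging series (matched on ``assessment_id``), and both
    cross-covariance LRTs are run.  Benjamini-Hochberg adjustment is
    applied across risks, separately per level.  Per-risk failures are
    reported as flagged rows rather than raised.
    """
    df = cohort.copy()
    df["_aging"] = df["assessment_id"].map(aging)
    rows = []
    fits = {}
    for risk in risks:
        fam = families[risk]
        note = ""
        try:
            mode = "mean" if fam == "continuous" else "rolling_sum"
            prepared = fill_cohort_risk(df, risk, mode)
            if fam == "continuous":
                prepared = pd.Series(winsorize(prepared, winsor_z), index=df.index)
            if np.nanstd(prepared.to_numpy(dtype=float)) == 0:
                raise ValueError(f"risk {risk!r} has zero variance")
            cov = df[covariate_cols] if covariate_cols else None
            model = BivariateMixedModel(
                df["_aging"].to_numpy(), prepared.to_numpy(dtype=float),
                df["subject_id"].to_numpy(), cov, reml=reml,
                quadratic_age=quadratic_age)
            fit = model.fit()
            fits[risk] = fit
            if fam == "binary":
                note = "binary risk modeled on the linear (0/1) scale"
            if fit.boundary:
                p_s = p_w = np.nan
                note = (note + "; " if note else "") + "boundary estimate, LRT skipped"
            else:
                p_s = fit.lrt("subject")["p"]
                p_w = fit.lrt("wave")["p"]
            rows.append({
                "risk": risk, "family": fam,
                "icc_aging": fit.icc_y1, "icc_risk": fit.icc_y2,
                "r_total": fit.r_total, "r_subject": fit.r_subject,
                "r_wave": fit.r_wave, "p_subject": p_s, "p_wave": p_w,
                "converged": fit.converged, "boundary": fit.boundary,
                "note": note,
            })
        except (ValueError, ConvergenceError) as exc:
            rows.append({"risk": risk, "family": fam, "icc_aging": np.nan,
                         "icc_risk": np.nan, "r_total": np.nan,
                         "r_subject": np.nan, "r_wave": np.nan,
                         "p_subject": np.nan, "p_wave": np.nan,
                         "converged": False, "boundary": False,
                         "note": f"error: {exc}"})
    table = pd.DataFrame(rows)
    for col in ("p_subject", "p_wave"):
        adj = np.full(len(table), np.nan)
        ok = table[col].notna().to_numpy()
        if ok.any():
            adj[ok] = bh_fdr(table.loc[ok, col].to_numpy())
        table[f"{col}_fdr"] = adj
    table.attrs["fits"] = fits
    return table
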