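"""Synthetic longitudinal cohort generator with known ground truth.

Emulates a prospective cohort followed from late childhood into
adulthood: each subject contributes 1-3 irregularly spaced assessment
waves between roughly 9 and 35 years of age, with childhood waves 1-3
years apart and the adult wave about a decade after the last childhood
wave.  At every wave we generate

* a latent *epigenetic-aging deviation* ``d_ij = u_i + w_ij`` in years,
  split into a subject-stable part ``u_i`` and a wave-specific part
  ``w_ij`` (both zero-mean Gaussian);
* health risks (counts, continuous values, binaries) tied to the latent
  deviation through a Gaussian copula so that the subject-level latent
  correlation equals ``rho_subject`` and the wave-level latent
  correlation equals ``rho_wave``;
* a site x assessment methylation score matrix on the semi-quantitative
  0-20 scale, where a configurable subset of sites carries a linear
  trend in *biological* age (chronological age plus the latent
  deviation) on top of subject-stable offsets and i.i.d. noise.

A configurable lagged effect adds ``lagged_b_months / 12 * risk_T2`` to
the adult-wave deviation, where ``risk_T2`` is the risk exposure at the
latest pre-adult wave (cumulative across childhood waves for count
risks, the observed value otherwise) — the quantity a lagged
change-score analysis regresses on.

Everything the generator draws is recorded in a :class:`GroundTruth`
object for use by tests and calibration studies; analysis code never
reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
from scipy import stats

from .data import CELL_COLS, SCORE_MAX, SCORE_MIN, MethylationMatrix

ADULT_AGE = 17.0
RISK_FAMILIES = ("count", "continuous", "binary")


@dataclass(frozen=True)
class RiskSpec:
    """One health risk and its true coupling to the latent aging deviation.

    ``mean`` is the Poisson mean for count risks, the marginal mean for
    continuous risks and the prevalence for binary risks.  ``icc`` is
    the proportion of the risk's latent variance that is subject-stable.
    ``rho_subject`` / ``rho_wave`` are the correlations between the
    risk's latent components and the corresponding components of the
    aging deviation.  ``lagged_b_months`` is the true lagged effect of
    the pre-adult exposure on the adult deviation, in months per risk
    unit.
    """

    name: str
    family: str
    mean: float = 0.0
    sd: float = 1.0
    icc: float = 0.4
    rho_subject: float = 0.0
    rho_wave: float = 0.0
    lagged_b_months: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in RISK_FAMILIES:
            raise ValueError(f"unknown risk family {self.family!r}")
        if not (-1.0 <= self.rho_subject <= 1.0 and -1.0 <= self.rho_wave <= 1.0):
            raise ValueError("rho_subject and rho_wave must lie in [-1, 1]")
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("risk icc must lie in [0, 1]")
        if self.family == "binary" and not 0.0 < self.mean < 1.0:
            raise ValueError("binary risk mean is a prevalence in (0, 1)")
        if self.family == "count" and self.mean <= 0:
            raise ValueError("count risk mean must be positive")
        if self.sd < 0:
            raise ValueError("risk sd must be non-negative")


def default_risks() -> tuple[RiskSpec, ...]:
    """Risk battery mirroring a psychiatric-epidemiology cohort.

    Counts (symptom/exposure tallies), one continuous anthropometric,
    and binary lifestyle/adversity indicators.  Stability (icc) is
    highest for BMI and childhood trauma, modest for the symptom scales.
    Defaults carry a subject-level BMI correlation of 0.15 with the
    aging deviation and a lagged depressive-symptom effect of 1.67
    months per symptom; all other couplings are null.
    """
    return (
        RiskSpec("depressive_symptoms", "count", mean=3.6, icc=0.30,
                 lagged_b_months=1.67),
        RiskSpec("anxiety_symptoms", "count", mean=2.0, icc=0.25),
        RiskSpec("childhood_trauma", "count", mean=1.2, icc=0.50),
        RiskSpec("functional_impairments", "count", mean=1.5, icc=0.30),
        RiskSpec("bmi", "continuous", mean=24.0, sd=5.0, icc=0.70,
                 rho_subject=0.15),
        RiskSpec("poverty", "binary", mean=0.25, icc=0.50),
        RiskSpec("smoking", "binary", mean=0.20, icc=0.40),
        RiskSpec("alcohol", "binary", mean=0.15, icc=0.30),
        RiskSpec("cannabis", "binary", mean=0.10, icc=0.30),
    )


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort.

    Waves-per-subject probabilities default to the observed mix of a
    cohort with 539 subjects contributing 1029 assessments (146 / 296 /
    97 subjects with 1 / 2 / 3 waves, i.e. 1.9 assessments per subject
    on average).  Methylation dimensions are scaled down from the tens
    of millions of sites an affinity-capture assay interrogates to a
    few hundred, keeping the signal structure (a minority of sites with
    real age trends among noise sites) intact.
    """

    n_subjects: int = 539
    wave_probs: tuple[float, float, float] = (0.271, 0.549, 0.180)
    age_range: tuple[float, float] = (9.0, 35.0)
    adult_gap_mean: float = 10.74     # years from last childhood wave to adult wave
    adult_gap_sd: float = 4.04
    n_sites: int = 400
    n_age_sites: int = 100
    age_slope_sd: float = 0.08        # score-units per year of biological age
    subject_offset_sd: float = 0.5    # score-units, subject-stable per site
    site_noise_sd: float = 1.0        # score-units, i.i.d. per cell
    aging_deviation_sd: float = 1.5   # years, total SD of the latent deviation
    aging_icc: float = 0.5            # subject-stable share of deviation variance
    risks: tuple[RiskSpec, ...] = field(default_factory=default_risks)
    covariate_effects: dict = field(default_factory=lambda: {
        "sex": 0.3, "cells": 3.0, "tech": 0.2})
    risk_missing_rate: float = 0.0
    round_scores: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        probs = np.asarray(self.wave_probs, dtype=float)
        if probs.shape != (3,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
            raise ValueError("wave_probs must be 3 non-negative probabilities summing to 1")
        if not 0 <= self.n_age_sites <= self.n_sites:
            raise ValueError("need 0 <= n_age_sites <= n_sites")
        for name in ("age_slope_sd", "subject_offset_sd", "site_noise_sd",
                     "aging_deviation_sd", "adult_gap_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.aging_icc <= 1.0:
            raise ValueError("aging_icc must lie in [0, 1]")
        if not 0.0 <= self.risk_missing_rate < 1.0:
            raise ValueError("risk_missing_rate must lie in [0, 1)")
        names = [r.name for r in self.risks]
        if len(set(names)) != len(names):
            raise ValueError("risk names must be unique")
        for level in ("subject", "wave"):
            corr = _copula_corr(self.risks, level)
            if np.linalg.eigvalsh(corr)[0] < -1e-10:
                raise ValueError(
                    f"implied {level}-level copula correlation matrix is not "
                    "positive semi-definite")


def _copula_corr(risks: tuple[RiskSpec, ...], level: str) -> np.ndarray:
    """Correlation matrix of (aging latent, risk latents) at one level.

    Risks are conditionally independent given the aging latent, so the
    off-diagonal between risks r and s is rho_r * rho_s.
    """
    rhos = np.array([r.rho_subject if level == "subject" else r.rho_wave
                     for r in risks])
    corr = np.outer(rhos, rhos)
    np.fill_diagonal(corr, 1.0)
    full = np.empty((len(rhos) + 1, len(rhos) + 1))
    full[0, 0] = 1.0
    full[0, 1:] = full[1:, 0] = rhos
    full[1:, 1:] = corr
    return full


@dataclass
class GroundTruth:
    """Everything the generator drew; consumed only by tests.

    Latent aging deviations are stored per assessment (aligned with the
    cohort rows) and split into their subject (``u``) and wave (``w``)
    parts.  For each risk the standardized subject- and wave-level
    latents are stored so moment oracles can check the target
    correlations, together with the true variance-decomposition
    contributions implied by the construction:
    ``contrib_subject = rho_subject * sqrt(icc_risk * aging_icc)`` and
    ``contrib_wave = rho_wave * sqrt((1 - icc_risk) * (1 - aging_icc))``.
    """

    deviation: np.ndarray          # per assessment, years (includes lagged term)
    u_subject: np.ndarray          # per subject, years
    w_wave: np.ndarray             # per assessment, years
    subject_index: np.ndarray      # per assessment -> subject position
    risk_truth: dict               # name -> dict of true parameters + latents
    site_slopes: np.ndarray        # per site, score-units / year
    site_baselines: np.ndarray     # per site, score-units
    aging_icc: float
    aging_deviation_sd: float

    def to_json(self, path) -> None:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, dict):
                return {k: conv(v) for k, v in x.items()}
            return x
        payload = {k: conv(v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _draw_ages(rng: np.random.Generator, n_waves: np.ndarray,
               config: SimulationConfig) -> list[np.ndarray]:
    """Assessment ages per subject: childhood waves 1-3 y apart, adult
    wave ~a decade later; single-wave subjects anywhere in range."""
    lo, hi = config.age_range
    ages = []
    for k in n_waves:
        if k == 1:
            ages.append(np.array([rng.uniform(lo, hi)]))
            continue
        if k == 2:
            child = np.array([rng.uniform(lo, ADULT_AGE - 1.0)])
        else:
            first = rng.uniform(lo, ADULT_AGE - 3.0)
            second = min(first + rng.uniform(1.0, 3.0), ADULT_AGE - 0.5)
            child = np.array([first, second])
        gap = rng.normal(config.adult_gap_mean, config.adult_gap_sd)
        adult = float(np.clip(child[-1] + gap, ADULT_AGE + 1.0, hi))
        ages.append(np.append(child, adult))
    return ages


def _risk_values(spec: RiskSpec, z: np.ndarray) -> np.ndarray:
    """Map a standard-normal latent to the risk's marginal family via
    its quantile function (Gaussian copula)."""
    if spec.family == "continuous":
        return spec.mean + spec.sd * z
    uni = stats.norm.cdf(z)
    if spec.family == "count":
        return stats.poisson.ppf(uni, spec.mean)
    return (uni > 1.0 - spec.mean).astype(float)


def generate_cohort(config: SimulationConfig, seed: int | None = None):
    """Generate a synthetic cohort.

    Returns ``(cohort, methylation, truth)``: the long-format cohort
    table, the site x assessment methylation score matrix, and the
    :class:`GroundTruth` record.  Identical config and seed give
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    n = config.n_subjects
    n_waves = rng.choice([1, 2, 3], size=n, p=np.asarray(config.wave_probs))
    ages_per_subject = _draw_ages(rng, n_waves, config)
    subject_index = np.repeat(np.arange(n), n_waves)
    wave_number = np.concatenate([np.arange(1, k + 1) for k in n_waves])
    age = np.concatenate(ages_per_subject)
    m = age.size

    sd_u = np.sqrt(config.aging_icc) * config.aging_deviation_sd
    sd_w = np.sqrt(1.0 - config.aging_icc) * config.aging_deviation_sd
    u = rng.normal(0.0, 1.0, size=n)            # standardized subject latent
    w = rng.normal(0.0, 1.0, size=m)            # standardized wave latent
    u_years = sd_u * u
    w_years = sd_w * w
    deviation = u_years[subject_index] + w_years

    # Health risks: latents correlated with (u, w), quantile-mapped
    subject_ids = np.array([f"S{i:04d}" for i in range(n)])
    assessment_ids = np.array(
        [f"{subject_ids[s]}_w{t}" for s, t in zip(subject_index, wave_number)])
    is_adult = age >= ADULT_AGE

    risk_cols: dict[str, np.ndarray] = {}
    risk_truth: dict[str, dict] = {}
    for spec in config.risks:
        za = spec.rho_subject * u + np.sqrt(1 - spec.rho_subject ** 2) * \
            rng.normal(0.0, 1.0, size=n)
        ze = spec.rho_wave * w + np.sqrt(1 - spec.rho_wave ** 2) * \
            rng.normal(0.0, 1.0, size=m)
        z = np.sqrt(spec.icc) * za[subject_index] + np.sqrt(1 - spec.icc) * ze
        values = _risk_values(spec, z)
        risk_cols[spec.name] = values
        risk_truth[spec.name] = {
            "family": spec.family,
            "rho_subject": spec.rho_subject,
            "rho_wave": spec.rho_wave,
            "lagged_b_months": spec.lagged_b_months,
            "icc": spec.icc,
            "contrib_subject": spec.rho_subject * np.sqrt(spec.icc * config.aging_icc),
            "contrib_wave": spec.rho_wave * np.sqrt(
                (1 - spec.icc) * (1 - config.aging_icc)),
            "subject_latent": za,
            "wave_latent": ze,
        }

    # Lagged effects: adult deviation += b/12 * pre-adult exposure
    lagged_exposure: dict[str, np.ndarray] = {}
    for spec in config.risks:
        if spec.lagged_b_months == 0.0:
            continue
        values = risk_cols[spec.name]
        exposure = np.full(n, np.nan)
        for i in range(n):
            rows = np.flatnonzero(subject_index == i)
            pre = rows[~is_adult[rows]]
            adult_rows = rows[is_adult[rows]]
            if pre.size == 0 or adult_rows.size == 0:
                continue
            if spec.family == "count":
                exposure[i] = values[pre].sum()     # cumulative childhood exposure
            else:
                exposure[i] = values[pre[-1]]
            deviation[adult_rows] += spec.lagged_b_months / 12.0 * exposure[i]
        lagged_exposure[spec.name] = exposure
    for name, exposure in lagged_exposure.items():
        risk_truth[name]["lagged_exposure_t2"] = exposure

    if config.risk_missing_rate > 0:
        for name, values in risk_cols.items():
            miss = rng.random(m) < config.risk_missing_rate
            # never blank a subject's only observation
            for i in range(n):
                rows = np.flatnonzero(subject_index == i)
                if miss[rows].all():
                    miss[rows[0]] = False
            vals = values.astype(float)
            vals[miss] = np.nan
            risk_cols[name] = vals

    # Covariates
    sex = rng.integers(0, 2, size=n)[subject_index]
    race = rng.choice(["white", "american_indian", "other"], size=n,
                      p=[0.65, 0.25, 0.10])[subject_index]
    tanner = np.where(
        is_adult, 5,
        np.clip(np.rint(1 + 4 * (age - 9.0) / 8.0 + rng.normal(0, 0.5, m)),
                1, 5)).astype(int)
    cells = rng.dirichlet(150.0 * np.array([0.25, 0.08, 0.57, 0.10]), size=m)
    tech = rng.normal(0.0, 1.0, size=(m, 2))

    cohort = pd.DataFrame({
        "subject_id": subject_ids[subject_index],
        "wave": wave_number,
        "assessment_id": assessment_ids,
        "age": age,
        "sex": sex,
        "race_ethnicity": race,
        "tanner": tanner,
        **{c: cells[:, i] for i, c in enumerate(CELL_COLS)},
        "tech1": tech[:, 0],
        "tech2": tech[:, 1],
        **risk_cols,
    })

    # Methylation: baseline + slope * centered biological age + offsets
    n_sites = config.n_sites
    slopes = np.zeros(n_sites)
    slopes[:config.n_age_sites] = rng.normal(0.0, config.age_slope_sd,
                                             config.n_age_sites)
    baselines = rng.uniform(4.0, 16.0, n_sites)
    age_center = 0.5 * (config.age_range[0] + config.age_range[1])
    bio_age = age + deviation

    if n_sites > 0:
        offsets = rng.normal(0.0, config.subject_offset_sd, size=(n_sites, n))
        noise = rng.normal(0.0, config.site_noise_sd, size=(n_sites, m))
        scores = (baselines[:, None]
                  + slopes[:, None] * (bio_age - age_center)[None, :]
                  + offsets[:, subject_index] + noise)
        eff = config.covariate_effects
        cov_block = np.column_stack([
            eff.get("sex", 0.0) * (sex - 0.5),
            *[eff.get("cells", 0.0) * (cells[:, i] - cells[:, i].mean())
              for i in range(4)],
            eff.get("tech", 0.0) * tech[:, 0],
            eff.get("tech", 0.0) * tech[:, 1],
        ])
        loadings = rng.normal(0.0, 1.0, size=(n_sites, cov_block.shape[1]))
        scores += loadings @ cov_block.T
        scores = np.clip(scores, SCORE_MIN, SCORE_MAX)
        if config.round_scores:
            scores = np.rint(scores)
    else:
        scores = np.empty((0, m))

    site_ids = [f"site{j:05d}" for j in range(n_sites)]
    meth = MethylationMatrix(site_ids, list(assessment_ids), scores)

    truth = GroundTruth(
        deviation=deviation, u_subject=u_years, w_wave=w_years,
        subject_index=subject_index, risk_truth=risk_truth,
        site_slopes=slopes, site_baselines=baselines,
        aging_icc=config.aging_icc,
        aging_deviation_sd=config.aging_deviation_sd,
    )
    return cohort, meth, truth
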