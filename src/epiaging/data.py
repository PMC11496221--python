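"""Containers and plain-text I/O for cohort and methylation data.

The two central tables are:

* the *cohort table* — long format, one row per subject x wave, holding
  chronological age, demographic covariates, estimated cell-type
  proportions, technical covariates and health-risk values;
* the *methylation matrix* — sites x assessments, semi-quantitative
  methylation scores on the 0-20 scale produced by affinity-capture
  sequencing (not array beta-values).

Both are serialized as tab-separated text so that fixtures and pipeline
intermediates stay human-readable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCORE_MIN = 0.0
SCORE_MAX = 20.0

#: columns every cohort table must carry
COHORT_REQUIRED = ("subject_id", "wave", "assessment_id", "age")

#: estimated blood cell-type proportion columns (T cells, monocytes,
#: granulocytes, B cells)
CELL_COLS = ("cd3", "cd14", "cd15", "cd19")


@dataclass
class MethylationMatrix:
    """Site x assessment matrix of semi-quantitative methylation scores.

    Parameters
    ----------
    site_ids : list of str
        Row labels (methylation sites).
    assessment_ids : list of str
        Column labels; must match the ``assessment_id`` column of the
        cohort table the matrix is joined to.
    scores : ndarray, shape (n_sites, n_assessments)
        Scores in ``[0, 20]``, no missing cells.
    """

    site_ids: list[str]
    assessment_ids: list[str]
    scores: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.site_ids), len(self.assessment_ids)):
            raise ValueError(
                f"scores shape {self.scores.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.assessment_ids)} assessments"
            )
        if np.isnan(self.scores).any():
            raise ValueError("methylation matrix contains missing cells")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_assessments(self) -> int:
        return len(self.assessment_ids)

    def subset_assessments(self, assessment_ids: list[str]) -> "MethylationMatrix":
        """Return a column subset in the requested order."""
        pos = {a: i for i, a in enumerate(self.assessment_ids)}
        idx = [pos[a] for a in assessment_ids]
        return MethylationMatrix(list(self.site_ids), list(assessment_ids),
                                 self.scores[:, idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.site_ids,
                            columns=self.assessment_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "site_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), list(df.columns.astype(str)),
                   df.to_numpy(dtype=float))


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the structural invariants of a long-format cohort table.

    Raises ``ValueError`` on: missing required columns, duplicate
    (subject, wave) keys, non-increasing age within subject, cell
    proportions outside [0, 1] or summing above 1, or pre-adult rows
    coded at the adult pubertal stage ceiling incorrectly (adult rows,
    age >= 17, must have Tanner stage 5).
    """
    missing = [c for c in COHORT_REQUIRED if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    dup = cohort.duplicated(subset=["subject_id", "wave"])
    if dup.any():
        raise ValueError("duplicate (subject_id, wave) rows in cohort table")
    for _, grp in cohort.groupby("subject_id", sort=False):
        ages = grp.sort_values("wave")["age"].to_numpy()
        if np.any(np.diff(ages) <= 0):
            raise ValueError("assessment age must be strictly increasing within subject")
    cells = [c for c in CELL_COLS if c in cohort.columns]
    if cells:
        vals = cohort[list(cells)].to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("cell proportions must lie in [0, 1]")
        if np.any(vals.sum(axis=1) > 1 + 1e-6):
            raise ValueError("cell proportions sum above 1 within a row")
    if "tanner" in cohort.columns:
        adult = cohort["age"] >= 17
        if (cohort.loc[adult, "tanner"] != 5).any():
            raise ValueError("adult rows (age >= 17) must have tanner == 5")


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    cohort = pd.read_csv(path, sep="\t")
    cohort["subject_id"] = cohort["subject_id"].astype(str)
    cohort["assessment_id"] = cohort["assessment_id"].astype(str)
    return cohort
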