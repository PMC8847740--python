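"""Longitudinal kinetic dataset container.

A :class:`KineticDataset` couples an observation table (one row per
transgene measurement) with a subject table (one row per subject: baseline
covariates, dose group, comedication first-administration times, response
label) and, for simulated cohorts, a ground-truth table carrying the
individual parameters and etas each subject was generated with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KineticDataset", "OBS_COLUMNS", "SUBJECT_COLUMNS"]

OBS_COLUMNS = ("ID", "TIME", "DV", "BLQ", "LOQ")
SUBJECT_COLUMNS = (
    "ID",
    "AGE",
    "SEX",
    "WT",
    "DOSE",
    "EMM",
    "PRIOR_CART",
    "PRIOR_HSCT",
    "CRS_GRADE",
    "TTOCI",
    "TSTER",
    "RESPONSE",
)


@dataclass
class KineticDataset:
    """Observations plus per-subject covariates (and optional ground truth).

    ``obs`` columns: ID, TIME (days), DV (copies/µg, may be NaN for censored
    records), BLQ (0/1), LOQ (copies/µg).  ``subjects`` columns follow
    :data:`SUBJECT_COLUMNS`; TTOCI/TSTER are NaN when the drug was not given.
    """

    obs: pd.DataFrame
    subjects: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in OBS_COLUMNS if c not in self.obs.columns]
        if missing:
            raise ValueError(f"observation table missing columns: {missing}")
        if "ID" not in self.subjects.columns:
            raise ValueError("subject table must have an ID column")
        obs_ids = set(self.obs["ID"].unique())
        sub_ids = set(self.subjects["ID"].unique())
        if not obs_ids <= sub_ids:
            raise ValueError(
                f"observations reference unknown subjects: {sorted(obs_ids - sub_ids)[:5]}"
            )
        if len(self.subjects) != len(sub_ids):
            raise ValueError("subject table has duplicated IDs")

    @property
    def subject_ids(self) -> np.ndarray:
        return self.subjects["ID"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.obs)

    @property
    def n_blq(self) -> int:
        return int((self.obs["BLQ"] != 0).sum())

    def observations_for(self, subject_id) -> pd.DataFrame:
        return self.obs[self.obs["ID"] == subject_id]

    def subset(self, subject_ids) -> "KineticDataset":
        ids = list(subject_ids)
        gt = None
        if self.ground_truth is not None:
            gt = self.ground_truth[self.ground_truth["ID"].isin(ids)].reset_index(drop=True)
        return KineticDataset(
            obs=self.obs[self.obs["ID"].isin(ids)].reset_index(drop=True),
            subjects=self.subjects[self.subjects["ID"].isin(ids)].reset_index(drop=True),
            ground_truth=gt,
        )

    def to_frame(self) -> pd.DataFrame:
        """Single NONMEM-style long table (covariates repeated on each row)."""
        return self.obs.merge(self.subjects, on="ID", how="left")

    def summary(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "n_blq": self.n_blq,
        }
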