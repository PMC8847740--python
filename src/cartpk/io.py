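"""Dataset file formats: NONMEM-style longitudinal CSV with covariates.

One row per observation; required columns ID, TIME, DV, BLQ, LOQ plus the
per-subject covariate columns (constant within ID).  A single administration
at t = 0 is implicit — there are no dosing/EVID rows.  Simulated ground truth
travels in a sidecar CSV keyed by subject ID.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .dataset import OBS_COLUMNS, SUBJECT_COLUMNS, KineticDataset

__all__ = ["read_dataset", "write_dataset", "DatasetSchemaError", "SCHEMA_COLUMNS"]

log = logging.getLogger("cartpk")

SCHEMA_COLUMNS = tuple(OBS_COLUMNS) + tuple(c for c in SUBJECT_COLUMNS if c != "ID")


class DatasetSchemaError(ValueError):
    """Schema violation with the offending rows listed."""

    def __init__(self, problems: list):
        self.problems = problems
        super().__init__("dataset schema violations:\n" + "\n".join(problems))


def write_dataset(data: KineticDataset, path, ground_truth_path=None) -> None:
    """Write the merged long-format CSV (and optionally the ground truth)."""
    data.to_frame().to_csv(path, index=False)
    if ground_truth_path is not None and data.ground_truth is not None:
        data.ground_truth.to_csv(ground_truth_path, index=False)


def read_dataset(path, ground_truth_path=None) -> KineticDataset:
    """Read and validate a NONMEM-style long-format CSV.

    Column matching is case-insensitive.  Violations (missing columns,
    duplicated ID x TIME rows, BLQ/DV inconsistencies, covariates varying
    within a subject) are collected and raised together with row numbers
    (1-based, excluding the header).
    """
    df = pd.read_csv(path)
    df.columns = [c.upper() for c in df.columns]
    problems = []
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetSchemaError([f"missing required columns: {missing}"])

    dup = df.duplicated(subset=["ID", "TIME"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        problems.append(f"duplicated ID x TIME rows at rows {rows}")
    neg = df["TIME"] < 0
    if neg.any():
        problems.append(f"negative TIME at rows {(df.index[neg] + 1).tolist()}")
    blq = df["BLQ"].fillna(0) != 0
    bad_blq = blq & df["DV"].notna() & (df["DV"] >= df["LOQ"])
    if bad_blq.any():
        problems.append(
            f"BLQ=1 with DV >= LOQ at rows {(df.index[bad_blq] + 1).tolist()}"
        )
    cov_cols = [c for c in SUBJECT_COLUMNS if c != "ID" and c in df.columns]
    for c in cov_cols:
        nun = df.groupby("ID")[c].nunique(dropna=False)
        varying = nun[nun > 1]
        if len(varying):
            problems.append(
                f"covariate {c} varies within subject(s) {varying.index.tolist()}"
            )
    if problems:
        raise DatasetSchemaError(problems)

    # missing DV on quantifiable rows: treated as missing-at-random, dropped
    drop = df["DV"].isna() & ~blq
    if drop.any():
        log.info("dropping %d rows with missing DV and BLQ=0", int(drop.sum()))
        df = df[~drop].reset_index(drop=True)

    obs = df[list(OBS_COLUMNS)].copy()
    obs["BLQ"] = obs["BLQ"].fillna(0).astype(int)
    subjects = (
        df[["ID"] + cov_cols].groupby("ID", as_index=False).first().reset_index(drop=True)
    )
    for c in SUBJECT_COLUMNS:
        if c not in subjects.columns:
            subjects[c] = np.nan
    gt = pd.read_csv(ground_truth_path) if ground_truth_path is not None else None
    return KineticDataset(obs=obs, subjects=subjects[list(SUBJECT_COLUMNS)], ground_truth=gt)
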