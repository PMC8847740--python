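"""Exposure-response, remission-rate summaries and clonal-diversity analytics.

Exposure-response fits a logistic regression of a binary clinical response on
dose; when the outcome is degenerate (e.g. every patient responding) the
slope is unidentifiable and a penalised fallback is reported instead.
Clonal structure is summarised from proportional clone-abundance tables:
major clones at the 3% abundance threshold, Simpson's reciprocal index
``1/sum(p_i^2)`` as the diversity measure, and per-subject diversity
trajectories with a configurable "salient drop" flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CloneAbundanceTable",
    "dose_response_logistic",
    "remission_rate",
    "simpson_reciprocal",
    "classify_clones",
    "diversity_trajectory",
]


@dataclass
class CloneAbundanceTable:
    """Proportional clone abundances of one sample.

    ``clones`` maps clone identifiers to proportional abundances; the
    abundances must be non-negative and sum to 1.
    """

    sample_id: str
    time_label: str
    clones: dict

    def __post_init__(self) -> None:
        p = np.array(list(self.clones.values()), dtype=float)
        if p.size == 0 or np.any(p < 0):
            raise ValueError("abundances must be a non-empty, non-negative set")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"abundances must sum to 1 (got {p.sum()!r})")

    @property
    def abundances(self) -> np.ndarray:
        return np.array(list(self.clones.values()), dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list:
        """Build tables from a long CSV layout
        (sample_id, time_label, clone_id, abundance)."""
        out = []
        for (sid, tl), g in df.groupby(["sample_id", "time_label"], sort=False):
            out.append(
                cls(
                    sample_id=str(sid),
                    time_label=str(tl),
                    clones=dict(zip(g["clone_id"], g["abundance"].astype(float))),
                )
            )
        return out


def dose_response_logistic(
    doses, responses, dose_as_category: bool = False
) -> dict:
    """Logistic regression of a binary response on dose.

    Returns per-dose observed response proportions (with binomial standard
    errors), the fitted slope on dose (in 10⁶ cells/kg units), its Wald
    trend p-value, and per-dose predicted probabilities.  With a degenerate
    outcome or complete separation an L2-penalised fit is substituted and
    flagged (``fallback=True``; no trend p-value).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size != y.size or d.size == 0:
        raise ValueError("doses and responses must be equal-length, non-empty")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("responses must be binary 0/1")
    levels = np.unique(d)
    if levels.size < 2:
        raise ValueError("need at least two dose levels")
    observed = []
    for lv in levels:
        m = d == lv
        p = y[m].mean()
        observed.append(
            {
                "dose": lv,
                "n": int(m.sum()),
                "responders": int(y[m].sum()),
                "p_obs": p,
                "se_obs": float(np.sqrt(p * (1 - p) / m.sum())),
            }
        )
    if dose_as_category:
        X = pd.get_dummies(pd.Categorical(d), drop_first=True, dtype=float).to_numpy()
        X = sm.add_constant(X)
    else:
        X = sm.add_constant(d)
    fallback = False
    slope = p_trend = np.nan
    pred = None
    degenerate = y.min() == y.max()
    try:
        if degenerate:
            raise ValueError("degenerate outcome")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(res.bse)) or np.any(res.bse > 1e3):
            raise ValueError("unstable standard errors (separation)")
        slope = float(res.params[1]) if not dose_as_category else np.nan
        p_trend = float(res.pvalues[1]) if not dose_as_category else np.nan
        pred = res.predict(X)
    except Exception:
        fallback = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
        slope = float(res.params[1]) if not dose_as_category else np.nan
        pred = res.predict(X)
    out_pred = {float(lv): float(np.mean(pred[d == lv])) for lv in levels}
    return {
        "observed": pd.DataFrame(observed),
        "slope": slope,
        "p_trend": p_trend if not fallback else np.nan,
        "predicted": out_pred,
        "fallback": fallback,
        "model": res,
    }


def remission_rate(group_labels, responses) -> pd.DataFrame:
    """Exact remission proportion per group with numerator/denominator."""
    g = pd.Series(group_labels)
    y = pd.Series(responses, dtype=float)
    if len(g) != len(y) or len(g) == 0:
        raise ValueError("labels and responses must be equal-length, non-empty")
    rows = []
    for label, idx in g.groupby(g).groups.items():
        yy = y.loc[idx]
        rows.append(
            {
                "group": label,
                "responders": int(yy.sum()),
                "n": int(len(yy)),
                "rate_pct": round(100.0 * yy.mean(), 2),
            }
        )
    return pd.DataFrame(rows)


def simpson_reciprocal(abundances) -> float:
    """Simpson's reciprocal diversity index ``1 / sum(p_i^2)``.

    Accepts a proportional-abundance vector or a
    :class:`CloneAbundanceTable`; raw (unnormalised) counts are normalised
    first — the index is scale-invariant.
    """
    if isinstance(abundances, CloneAbundanceTable):
        p = abundances.abundances
    else:
        p = np.asarray(abundances, dtype=float)
    if p.size == 0 or np.any(p < 0) or p.sum() <= 0:
        raise ValueError("need a non-empty, non-negative abundance vector")
    p = p / p.sum()
    return float(1.0 / np.sum(p**2))


def classify_clones(
    sample: CloneAbundanceTable, threshold: float = 0.03, top_k: int = 3
) -> pd.DataFrame:
    """Label the top-``top_k`` clones at/above the abundance threshold.

    Clones with proportional abundance >= ``threshold`` are ranked by
    abundance and the first ``top_k`` labelled ``major-1..k``; everything
    else (including above-threshold clones beyond rank ``top_k``) is pooled
    as ``low-abundant``.  The output abundances conserve the input total.
    """
    items = sorted(sample.clones.items(), key=lambda kv: (-kv[1], str(kv[0])))
    rows = []
    pooled = 0.0
    rank = 0
    for clone, p in items:
        if p >= threshold and rank < top_k:
            rank += 1
            rows.append({"label": f"major-{rank}", "clone_id": clone, "abundance": p})
        else:
            pooled += p
    rows.append({"label": "low-abundant", "clone_id": None, "abundance": pooled})
    return pd.DataFrame(rows)


def diversity_trajectory(
    tables, drop_fraction: float = 0.2
) -> dict:
    """Simpson's-reciprocal time course for one subject, with a drop flag.

    ``tables`` are the subject's per-timepoint abundance tables in
    chronological order.  A "salient drop" is declared when any index after
    the first time point falls below ``drop_fraction`` of the running
    maximum of the preceding indices; with a single time point the flag is
    undefined (None).
    """
    tables = list(tables)
    if not tables:
        raise ValueError("need at least one abundance table")
    series = pd.Series(
        [simpson_reciprocal(t) for t in tables],
        index=[t.time_label for t in tables],
        name="simpson_reciprocal",
    )
    if len(series) < 2:
        return {"series": series, "drop": None}
    vals = series.to_numpy()
    running_max = np.maximum.accumulate(vals)[:-1]
    drop = bool(np.any(vals[1:] < drop_fraction * running_max))
    return {"series": series, "drop": drop}
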