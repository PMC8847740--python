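"""Model qualification: pcVPC, predictions and conditional weighted residuals.

The prediction-corrected visual predictive check simulates many replicate
datasets at the exact design of the input data (times, covariates,
comedication schedules), normalises observed and simulated values by the
bin-wise typical population prediction, and compares observed percentiles
with the simulation envelopes.  Conditional weighted residuals follow the
first-order-conditional linearisation at each subject's empirical-Bayes
etas and are approximately standard normal under a correctly specified
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import KineticDataset
from .model import PARAM_NAMES, PopulationModel, cv_to_omega
from .nlme import FitResult, LaplaceObjective, ModelSpec, _Packed

__all__ = ["VpcResult", "pcvpc", "predictions", "cwres"]


def _objective_for(data: KineticDataset, pop: PopulationModel, spec: ModelSpec | None):
    if spec is None:
        active = tuple(k for k in PARAM_NAMES if pop.omega_cv.get(k, 0.0) > 0)
        spec = ModelSpec(
            covariate_terms=pop.covariate_effects,
            random_effects=active or PARAM_NAMES,
            estimate_comedication=(pop.f1 != 1.0 or pop.f2 != 1.0),
        )
    packed = _Packed(data, spec)
    obj = LaplaceObjective(packed, spec)
    x = obj.x_from_pop(pop)
    return obj, packed, obj.unpack(x), spec


def _resolve(fit_or_pop, data, spec):
    if isinstance(fit_or_pop, FitResult):
        return fit_or_pop.pop, fit_or_pop.data if data is None else data, (
            spec or fit_or_pop.spec
        )
    if data is None:
        raise ValueError("a dataset is required when passing a bare population model")
    return fit_or_pop, data, spec


@dataclass
class VpcResult:
    """Observed percentiles and simulation envelopes per time bin."""

    bin_edges: np.ndarray
    stats: pd.DataFrame  # bin, statistic, observed, env_lo, env_hi, n_obs
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        return self.stats.copy()

    def coverage(self, statistic: str = "median") -> float:
        """Fraction of bins whose observed statistic lies inside its envelope."""
        s = self.stats[self.stats["statistic"] == statistic]
        inside = (s["observed"] >= s["env_lo"]) & (s["observed"] <= s["env_hi"])
        return float(inside.mean())


def predictions(fit_or_pop, data: KineticDataset | None = None, spec=None) -> pd.DataFrame:
    """Population (eta = 0) and individual (eta = EBE) predictions per record."""
    pop, data, spec = _resolve(fit_or_pop, data, spec)
    obj, packed, pars, spec = _objective_for(data, pop, spec)
    cov_mult = obj._cov_mult(pars)
    zeros = np.zeros((packed.n_subjects, obj.k_eta))
    pred = obj._conc(zeros, pars, cov_mult)
    etas, _ = obj._inner(pars, cov_mult)
    ipred = obj._conc(etas, pars, cov_mult)
    rows = []
    for i in range(packed.n_subjects):
        sel = packed.mask[i]
        rows.append(
            pd.DataFrame(
                {
                    "ID": packed.ids[i],
                    "TIME": packed.t[i, sel],
                    "DV": np.where(packed.blq[i, sel], np.nan, packed.y[i, sel]),
                    "BLQ": packed.blq[i, sel].astype(int),
                    "PRED": pred[i, sel],
                    "IPRED": ipred[i, sel],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def pcvpc(
    fit_or_pop,
    data: KineticDataset | None = None,
    n_sim: int = 1000,
    bins: int | np.ndarray = 8,
    seed: int = 0,
    spec: ModelSpec | None = None,
    percentiles=(2.5, 50.0, 97.5),
    envelope: float = 90.0,
) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicates of the dataset at its exact design,
    prediction-corrects observed and simulated values by the bin median of
    the population prediction, and returns the observed percentiles together
    with the ``envelope``% confidence band of each percentile across
    replicates.  Only records with a quantifiable observation enter the
    percentile computation; simulated values below the quantitation limit
    enter uncensored.
    """
    pop, data, spec = _resolve(fit_or_pop, data, spec)
    obj, packed, pars, spec = _objective_for(data, pop, spec)
    cov_mult = obj._cov_mult(pars)
    zeros = np.zeros((packed.n_subjects, obj.k_eta))
    pred = obj._conc(zeros, pars, cov_mult)

    sel = packed.quant  # quantifiable observed records
    times = packed.t[sel]
    y_obs = packed.y[sel]
    pred_rec = pred[sel]
    if np.isscalar(bins):
        qs = np.linspace(0, 1, int(bins) + 1)
        edges = np.unique(np.quantile(times, qs))
        if edges.size < 2:  # degenerate design: all records at one time
            edges = np.array([times.min() - 0.5, times.max() + 0.5])
    else:
        edges = np.asarray(bins, dtype=float)
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)

    # bin-median population prediction -> correction factor per record
    pc_factor = np.empty_like(pred_rec)
    for b in range(len(edges) - 1):
        m = bin_idx == b
        if m.any():
            pc_factor[m] = np.median(pred_rec[m]) / pred_rec[m]
    y_pc = y_obs * pc_factor

    rng = np.random.default_rng(seed)
    omega = np.array([cv_to_omega(pop.omega_cv.get(k, 0.0)) for k in spec.random_effects])
    sp = pop.sigma_prop / 100.0
    sa = pop.sigma_add
    n, m = packed.t.shape
    n_stats = len(percentiles)
    sim_stats = np.full((n_sim, len(edges) - 1, n_stats), np.nan)
    for r in range(n_sim):
        z = rng.standard_normal((n, obj.k_eta))
        etas = z * omega[None, :]
        f = obj._conc(etas, pars, cov_mult)
        eps_p = rng.standard_normal((n, m)) * sp
        eps_a = rng.standard_normal((n, m)) * sa
        y_sim = (f * (1.0 + eps_p) + eps_a)[sel] * pc_factor
        for b in range(len(edges) - 1):
            mask = bin_idx == b
            if mask.any():
                sim_stats[r, b, :] = np.percentile(y_sim[mask], percentiles)
    lo_q, hi_q = (100.0 - envelope) / 2.0, 100.0 - (100.0 - envelope) / 2.0
    rows = []
    names = {2.5: "p2.5", 50.0: "median", 97.5: "p97.5"}
    for b in range(len(edges) - 1):
        mask = bin_idx == b
        if not mask.any():
            continue
        obs_stats = np.percentile(y_pc[mask], percentiles)
        for j, q in enumerate(percentiles):
            rows.append(
                {
                    "bin": b,
                    "t_lo": edges[b],
                    "t_hi": edges[b + 1],
                    "statistic": names.get(q, f"p{q}"),
                    "observed": obs_stats[j],
                    "env_lo": np.nanpercentile(sim_stats[:, b, j], lo_q),
                    "env_hi": np.nanpercentile(sim_stats[:, b, j], hi_q),
                    "n_obs": int(mask.sum()),
                }
            )
    return VpcResult(bin_edges=edges, stats=pd.DataFrame(rows), n_sim=n_sim)


def cwres(fit_or_pop, data: KineticDataset | None = None, spec=None) -> pd.DataFrame:
    """Conditional weighted residuals (FOCE linearisation at the EBEs).

    For each subject, ``y ~ N(f(eta_hat) - G·eta_hat, G·Omega·G' + V)`` with
    ``G`` the model Jacobian in eta at the conditional mode and ``V`` the
    residual variance at the individual prediction; CWRES is the Cholesky
    whitening of the corresponding residual.  BLQ records get NaN (no
    quantified residual); subjects with a singular covariance are flagged.
    """
    pop, data, spec = _resolve(fit_or_pop, data, spec)
    obj, packed, pars, spec = _objective_for(data, pop, spec)
    cov_mult = obj._cov_mult(pars)
    etas, _ = obj._inner(pars, cov_mult)
    f_hat = obj._conc(etas, pars, cov_mult)
    d = 1e-5
    G = np.empty(f_hat.shape + (obj.k_eta,))
    for k in range(obj.k_eta):
        e = np.zeros(obj.k_eta)
        e[k] = d
        G[..., k] = (
            obj._conc(etas + e, pars, cov_mult) - obj._conc(etas - e, pars, cov_mult)
        ) / (2 * d)
    omega2 = pars.omega**2
    v = obj._variance(f_hat, pars)
    pred = obj._conc(np.zeros((packed.n_subjects, obj.k_eta)), pars, cov_mult)
    rows = []
    for i in range(packed.n_subjects):
        sel = packed.quant[i]
        out = np.full(int(packed.mask[i].sum()), np.nan)
        flagged = False
        if sel.any():
            Gi = G[i, sel, :]
            cov = Gi @ np.diag(omega2) @ Gi.T + np.diag(v[i, sel])
            resid = packed.y[i, sel] - (f_hat[i, sel] - Gi @ etas[i])
            try:
                L = np.linalg.cholesky(cov)
                cw = np.linalg.solve(L, resid)
            except np.linalg.LinAlgError:
                flagged = True
                cw = np.full(sel.sum(), np.nan)
            out[sel[packed.mask[i]]] = cw
        mask_i = packed.mask[i]
        rows.append(
            pd.DataFrame(
                {
                    "ID": packed.ids[i],
                    "TIME": packed.t[i, mask_i],
                    "CWRES": out,
                    "PRED": pred[i, mask_i],
                    "singular": flagged,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
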