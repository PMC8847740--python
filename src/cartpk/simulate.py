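"""Synthetic study-like cohorts with known ground truth.

The generator emulates the design of the 18-patient dose-escalation study the
reference parameterization comes from: doses of 1, 3 and 6 ×10⁶ CAR-positive
T cells/kg (9/6/3 subjects), extramedullary disease in 5/18 subjects,
tocilizumab in 11/18 and corticosteroids in 12/18 for CRS management, an
assay quantitation limit of 20 copies/µg gDNA, and sampling from infusion to
one year.  Between-subject variability and residual error default to the
reference (study-estimate) magnitudes, so downstream estimation can be
validated against known truth.

Each subject owns independent RNG substreams (covariates, etas, residuals,
comedication timing) spawned from the master seed, so changing one prevalence
never reshuffles unrelated subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import KineticDataset
from .kinetics import IndividualParams, _conc_arrays
from .model import PARAM_NAMES, CovariateTerm, PopulationModel, individual_param_matrix

__all__ = [
    "CohortConfig",
    "reference_population_model",
    "DEFAULT_SCHEDULE",
    "sample_individual_params",
    "simulate_observations",
    "generate_cohort",
]

#: default visit schedule (days): dense around expansion/peak, sparse to 1 year
DEFAULT_SCHEDULE = (0.0, 4.0, 7.0, 10.0, 14.0, 21.0, 28.0, 60.0, 90.0, 180.0, 270.0, 365.0)

# reference (study-estimate) parameterization of the modified model
_REF_THETA = {
    "c_max": 67060.0,
    "t_max": 8.657,
    "foldx": 5460.0,
    "fb": 0.1172,
    "alpha": 0.1093,
    "beta": 0.006122,
}
_REF_OMEGA_CV = {
    "c_max": 59.49,
    "t_max": 29.01,
    "foldx": 215.6,
    "fb": 154.0,
    "alpha": 73.49,
    "beta": 107.3,
}
_REF_SIGMA_PROP = 47.01  # %
_REF_SIGMA_ADD = 0.319  # copies/µg
_REF_THETA_EMM = 0.468
_REF_F1 = 0.966
_REF_F2 = 0.944


def reference_population_model(
    emm_effect: bool = True, comedication: bool = False
) -> PopulationModel:
    """Population model at the reference (study) estimates.

    ``emm_effect`` includes the extramedullary multiplier 0.468 on ``c_max``;
    ``comedication`` sets the tocilizumab/corticosteroid expansion-rate
    multipliers to their estimated values (0.966, 0.944) instead of 1.
    """
    terms = (
        (CovariateTerm("c_max", "EMM", "categorical", _REF_THETA_EMM),)
        if emm_effect
        else ()
    )
    return PopulationModel(
        theta=dict(_REF_THETA),
        omega_cv=dict(_REF_OMEGA_CV),
        sigma_prop=_REF_SIGMA_PROP,
        sigma_add=_REF_SIGMA_ADD,
        covariate_effects=terms,
        f1=_REF_F1 if comedication else 1.0,
        f2=_REF_F2 if comedication else 1.0,
    )


@dataclass(frozen=True)
class CohortConfig:
    """Design of a simulated cohort.

    Defaults emulate the 18-patient study; probabilities are per-subject
    Bernoulli draws, so realized counts vary around ``n·p``.  Dose groups are
    allocated deterministically by largest remainder so the configured
    proportions are met exactly.
    """

    n_subjects: int = 18
    dose_allocation: dict = field(
        default_factory=lambda: {1.0: 9 / 18, 3.0: 6 / 18, 6.0: 3 / 18}
    )
    emm_prevalence: float = 5 / 18
    prior_cart_prevalence: float = 4 / 18
    prior_hsct_prevalence: float = 6 / 18
    toci_prob: float = 11 / 18
    ster_prob: float = 12 / 18
    comed_time_low: float = 1.0
    comed_time_high: float = 7.0
    sampling_schedule: tuple = DEFAULT_SCHEDULE
    loq: float = 20.0
    response_prob: float = 0.78
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        for name in (
            "emm_prevalence",
            "prior_cart_prevalence",
            "prior_hsct_prevalence",
            "toci_prob",
            "ster_prob",
            "response_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        sched = tuple(float(t) for t in self.sampling_schedule)
        if any(t < 0 for t in sched) or list(sched) != sorted(sched):
            raise ValueError("sampling_schedule must be sorted and non-negative")
        object.__setattr__(self, "sampling_schedule", sched)
        if not self.loq > 0:
            raise ValueError("loq must be positive")
        total = sum(self.dose_allocation.values())
        if not np.isclose(total, 1.0):
            raise ValueError("dose_allocation proportions must sum to 1")


def _draw_etas(
    pop: PopulationModel, rng: np.random.Generator, fb_eta_scale: str, max_tries: int = 200
):
    """One eta vector; redraw the rare crossings that break parameter order.

    Draws with ``beta_i >= alpha_i``, ``foldx_i <= 1`` or (under the
    exponential fb convention) ``fb_i >= 1`` are rejected — at the reference
    magnitudes fewer than 1% of draws — so every simulated subject satisfies
    the structural-parameter invariants.
    """
    omega = pop.omega_vector
    theta = pop.theta_vector
    for _ in range(max_tries):
        eta = rng.standard_normal(len(PARAM_NAMES)) * omega
        row = individual_param_matrix(
            theta, eta[None, :], fb_eta_scale=fb_eta_scale
        )[0]
        names = dict(zip(PARAM_NAMES, row))
        if (
            names["beta"] < names["alpha"]
            and names["foldx"] > 1
            and 0 < names["fb"] < 1
        ):
            return eta
    raise RuntimeError("could not draw admissible etas; omegas may be implausible")


def _sample_params_and_etas(pop: PopulationModel, covariates, rng, fb_eta_scale="logit"):
    eta = _draw_etas(pop, rng, fb_eta_scale)
    subjects = pd.DataFrame([dict(covariates)])
    mult = pop.covariate_multipliers(subjects)
    row = individual_param_matrix(
        pop.theta_vector, eta[None, :], mult, fb_eta_scale=fb_eta_scale
    )[0]
    return IndividualParams(**dict(zip(PARAM_NAMES, row))), eta


def sample_individual_params(
    pop: PopulationModel, covariates: dict | pd.Series, rng_seed
) -> IndividualParams:
    """Draw one subject's structural parameters.

    Each parameter is ``theta·exp(eta)`` with ``eta ~ N(0, omega²)`` (``fb``
    on the logit scale, see :mod:`cartpk.model`); covariate effect terms
    multiply the typical value first, e.g. ``c_max·0.468`` for an
    extramedullary subject.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return _sample_params_and_etas(pop, covariates, rng)[0]


def simulate_observations(
    p: IndividualParams,
    schedule,
    sigma_prop: float,
    sigma_add: float,
    loq: float,
    rng_seed,
    t_toci: float | None = None,
    t_ster: float | None = None,
    f1: float = 1.0,
    f2: float = 1.0,
) -> pd.DataFrame:
    """Noisy observations of one subject on a visit schedule.

    ``dv = f(t)·(1 + eps_prop) + eps_add`` with ``eps_prop ~ N(0,
    (sigma_prop/100)²)`` and ``eps_add ~ N(0, sigma_add²)``; values below
    ``loq`` are flagged BLQ and retained as censored records.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    t = np.asarray(schedule, dtype=float)
    tt = np.inf if t_toci is None or np.isnan(t_toci) else t_toci
    ts = np.inf if t_ster is None or np.isnan(t_ster) else t_ster
    t1, t2 = min(tt, ts), max(tt, ts)
    m1 = (f1 if tt <= ts else f2) if np.isfinite(t1) else 1.0
    m12 = f1 * f2 if np.isfinite(t2) else m1
    f = _conc_arrays(
        t, p.c_max, p.t_max, p.foldx, p.fb, p.alpha, p.beta, t1=t1, m1=m1, t2=t2, m12=m12
    )
    eps_p = rng.standard_normal(t.size) * (sigma_prop / 100.0)
    eps_a = rng.standard_normal(t.size) * sigma_add
    dv = f * (1.0 + eps_p) + eps_a
    # a non-finite limit disables censoring entirely
    blq = (dv < loq) if np.isfinite(loq) else np.zeros_like(dv, dtype=bool)
    return pd.DataFrame(
        {"TIME": t, "DV": dv, "BLQ": blq.astype(int), "LOQ": float(loq), "F_TRUE": f}
    )


def _dose_counts(allocation: dict, n: int) -> list:
    """Largest-remainder allocation of n subjects over the dose groups."""
    doses = sorted(allocation)
    exact = np.array([allocation[d] * n for d in doses])
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out = []
    for d, c in zip(doses, counts):
        out.extend([d] * int(c))
    return out


def generate_cohort(cfg: CohortConfig, pop: PopulationModel) -> KineticDataset:
    """Simulate a complete longitudinal cohort with ground truth attached.

    Covariates are drawn per the configured prevalences, individual
    parameters from the population model (including covariate effects),
    and observations with combined residual error and BLQ censoring at the
    configured quantitation limit.
    """
    n = cfg.n_subjects
    children = np.random.SeedSequence(cfg.seed).spawn(n)
    doses = _dose_counts(cfg.dose_allocation, n)
    subj_rows, obs_frames, gt_rows = [], [], []
    sp_frac_pct, sa = pop.sigma_prop, pop.sigma_add
    for i in range(n):
        cov_rng, eta_rng, res_rng, comed_rng = (
            np.random.default_rng(s) for s in children[i].spawn(4)
        )
        # fixed draw order so prevalence changes never shift later draws
        age = float(np.clip(cov_rng.normal(53.5, 8.0), 30.0, 78.0))
        sex = int(cov_rng.random() < 10 / 18)
        wt = float(np.clip(cov_rng.normal(62.0, 10.0), 40.0, 95.0))
        u_emm = cov_rng.random()
        u_cart = cov_rng.random()
        u_hsct = cov_rng.random()
        crs = int(cov_rng.choice(5, p=[1 / 18, 6 / 18, 6 / 18, 4 / 18, 1 / 18]))
        u_resp = cov_rng.random()
        emm = int(u_emm < cfg.emm_prevalence)
        covariates = {
            "AGE": age,
            "SEX": sex,
            "WT": wt,
            "DOSE": doses[i],
            "EMM": emm,
            "PRIOR_CART": int(u_cart < cfg.prior_cart_prevalence),
            "PRIOR_HSCT": int(u_hsct < cfg.prior_hsct_prevalence),
            "CRS_GRADE": crs,
            "RESPONSE": int(u_resp < cfg.response_prob),
        }
        u_toci, u_ster = comed_rng.random(2)
        w_toci, w_ster = comed_rng.uniform(cfg.comed_time_low, cfg.comed_time_high, 2)
        t_toci = float(w_toci) if u_toci < cfg.toci_prob else np.nan
        t_ster = float(w_ster) if u_ster < cfg.ster_prob else np.nan

        params, eta = _sample_params_and_etas(pop, covariates, eta_rng)
        obs = simulate_observations(
            params,
            cfg.sampling_schedule,
            sp_frac_pct,
            sa,
            cfg.loq,
            res_rng,
            t_toci=t_toci,
            t_ster=t_ster,
            f1=pop.f1,
            f2=pop.f2,
        )
        sid = i + 1
        obs.insert(0, "ID", sid)
        obs_frames.append(obs)
        subj_rows.append({"ID": sid, **covariates, "TTOCI": t_toci, "TSTER": t_ster})
        gt_rows.append(
            {
                "ID": sid,
                **{f"true_{k}": getattr(params, k) for k in PARAM_NAMES},
                **{f"eta_{k}": eta[j] for j, k in enumerate(PARAM_NAMES)},
            }
        )
    obs = pd.concat(obs_frames, ignore_index=True)
    obs = obs.drop(columns=["F_TRUE"])
    return KineticDataset(
        obs=obs,
        subjects=pd.DataFrame(subj_rows)[
            [
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
            ]
        ],
        ground_truth=pd.DataFrame(gt_rows),
    )
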