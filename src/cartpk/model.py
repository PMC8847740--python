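"""Population-level model description shared by simulation and estimation.

A :class:`PopulationModel` holds the fixed effects (typical values of the six
structural parameters), between-subject variability expressed as %CV of
log-normal random effects, a combined proportional + additive residual-error
model, covariate effect terms, and comedication expansion-rate multipliers.

Conventions
-----------
* Random effects are exponential: ``p_i = theta_p · exp(eta_p)`` with
  ``eta_p ~ N(0, omega_p^2)`` and ``omega^2 = ln(1 + (CV/100)^2)``.
* ``fb`` is bounded in (0, 1); its eta acts on the logit scale
  (``fb_i = expit(logit(fb) + eta)``), which matches ``fb·exp(eta)`` to
  first order for small ``fb`` while keeping every realisation inside the
  unit interval; a pure exponential scale is available as an option.
* Residual error acts on the natural concentration scale by default:
  ``y = f·(1 + eps_prop) + eps_add``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "PARAM_NAMES",
    "CovariateTerm",
    "PopulationModel",
    "cv_to_omega",
    "omega_to_cv",
    "individual_param_matrix",
]

#: canonical ordering of the six structural parameters
PARAM_NAMES = ("c_max", "t_max", "foldx", "fb", "alpha", "beta")


def cv_to_omega(cv_percent: float) -> float:
    """SD of a log-normal eta whose coefficient of variation is ``cv_percent`` %."""
    if cv_percent < 0:
        raise ValueError(f"CV must be non-negative, got {cv_percent!r}")
    return math.sqrt(math.log1p((cv_percent / 100.0) ** 2))


def omega_to_cv(omega_sd: float) -> float:
    """Inverse of :func:`cv_to_omega` (%CV of ``exp(eta)``)."""
    if omega_sd < 0:
        raise ValueError(f"omega must be non-negative, got {omega_sd!r}")
    return 100.0 * math.sqrt(math.expm1(omega_sd**2))


@dataclass(frozen=True)
class CovariateTerm:
    """One covariate–parameter relation.

    ``form="categorical"`` multiplies the typical parameter value by
    ``theta`` for subjects whose (0/1) covariate is set;
    ``form="power"`` multiplies by ``(cov/ref)**theta`` for a continuous
    covariate with reference value ``ref`` (cohort median when left unset).
    """

    parameter: str
    covariate: str
    form: str = "categorical"
    theta: float = 1.0
    ref: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in PARAM_NAMES:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.form not in ("categorical", "power"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.form == "categorical" and not self.theta > 0:
            raise ValueError("categorical covariate multiplier must be positive")
        if self.form == "power" and self.ref is not None and not self.ref > 0:
            raise ValueError("power covariate reference must be positive")

    @property
    def label(self) -> str:
        return f"{self.covariate}->{self.parameter}"

    def multiplier(self, values: np.ndarray, ref: float | None = None) -> np.ndarray:
        """Per-subject multiplier on the typical parameter value."""
        values = np.asarray(values, dtype=float)
        if self.form == "categorical":
            return np.where(values != 0, self.theta, 1.0)
        r = self.ref if self.ref is not None else ref
        if r is None or not r > 0:
            raise ValueError(f"power term {self.label} needs a positive reference value")
        return (values / r) ** self.theta


@dataclass(frozen=True)
class PopulationModel:
    """Fixed effects, between-subject variability and residual error.

    Parameters
    ----------
    theta : dict
        Typical values of the six structural parameters (see
        :data:`PARAM_NAMES`), units as in
        :class:`~cartpk.kinetics.IndividualParams`.
    omega_cv : dict
        Between-subject variability per parameter as %CV of the log-normal
        random effect; parameters may be omitted (no variability).
    sigma_prop : float
        Proportional residual error, percent.
    sigma_add : float
        Additive residual error, copies/µg.
    covariate_effects : tuple of CovariateTerm
    f1, f2 : float
        Expansion-rate multipliers engaging at the first tocilizumab and
        corticosteroid administrations.
    """

    theta: dict
    omega_cv: dict = field(default_factory=dict)
    sigma_prop: float = 0.0
    sigma_add: float = 0.0
    covariate_effects: tuple = ()
    f1: float = 1.0
    f2: float = 1.0

    def __post_init__(self) -> None:
        missing = [k for k in PARAM_NAMES if k not in self.theta]
        if missing:
            raise ValueError(f"theta missing parameters: {missing}")
        unknown = [k for k in self.theta if k not in PARAM_NAMES]
        unknown += [k for k in self.omega_cv if k not in PARAM_NAMES]
        if unknown:
            raise ValueError(f"unknown parameter names: {unknown}")
        if any(v < 0 for v in self.omega_cv.values()):
            raise ValueError("omega CVs must be non-negative")
        if self.sigma_prop < 0 or self.sigma_add < 0:
            raise ValueError("residual-error components must be non-negative")
        if not (self.f1 > 0 and self.f2 > 0):
            raise ValueError("comedication multipliers must be positive")
        object.__setattr__(self, "covariate_effects", tuple(self.covariate_effects))

    @property
    def theta_vector(self) -> np.ndarray:
        return np.array([self.theta[k] for k in PARAM_NAMES], dtype=float)

    @property
    def omega_vector(self) -> np.ndarray:
        """Per-parameter eta SDs (log scale), ordered as :data:`PARAM_NAMES`."""
        return np.array(
            [cv_to_omega(self.omega_cv.get(k, 0.0)) for k in PARAM_NAMES], dtype=float
        )

    def with_covariate(self, term: CovariateTerm) -> "PopulationModel":
        return replace(self, covariate_effects=self.covariate_effects + (term,))

    def covariate_multipliers(self, subjects: "pd.DataFrame") -> np.ndarray:
        """(n_subjects, 6) matrix of covariate multipliers on theta.

        Power terms without an explicit reference use the cohort median of
        the covariate column.
        """
        n = len(subjects)
        mult = np.ones((n, len(PARAM_NAMES)))
        for term in self.covariate_effects:
            if term.covariate not in subjects.columns:
                raise KeyError(
                    f"covariate {term.covariate!r} not found in subject table"
                )
            values = subjects[term.covariate].to_numpy(dtype=float)
            ref = float(np.nanmedian(values)) if term.form == "power" else None
            j = PARAM_NAMES.index(term.parameter)
            mult[:, j] *= term.multiplier(values, ref=ref)
        return mult


def individual_param_matrix(
    theta_vec: np.ndarray,
    etas: np.ndarray,
    cov_mult: np.ndarray | None = None,
    fb_eta_scale: str = "logit",
) -> np.ndarray:
    """Map population typical values + etas to per-subject parameter rows.

    ``theta_vec`` is ordered as :data:`PARAM_NAMES`; ``etas`` is (n, 6);
    ``cov_mult`` an optional (n, 6) matrix of covariate multipliers applied to
    the typical value before the eta.  All parameters use ``theta·exp(eta)``
    except ``fb``, whose eta acts on the logit scale by default so the
    realised fraction stays inside (0, 1) and the mapping remains smooth in
    ``eta`` (``"exp"`` applies the unbounded exponential convention instead).
    """
    etas = np.atleast_2d(np.asarray(etas, dtype=float))
    base = theta_vec[None, :] * (np.ones_like(etas) if cov_mult is None else cov_mult)
    out = base * np.exp(etas)
    j = PARAM_NAMES.index("fb")
    if fb_eta_scale == "logit":
        out[:, j] = expit(logit(np.clip(base[:, j], 1e-12, 1 - 1e-12)) + etas[:, j])
    elif fb_eta_scale != "exp":
        raise ValueError(f"unknown fb eta scale {fb_eta_scale!r}")
    return out
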