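"""Closed-form cellular-kinetic model of CAR T-cell transgene concentration.

The structural model describes transgene copy number in peripheral blood
(copies/µg genomic DNA) after a single infusion at t = 0:

* exponential expansion at rate ``rho = ln(foldx)/t_max`` from a baseline of
  ``c_max/foldx`` up to the peak ``c_max`` reached at ``t_max``;
* biexponential contraction afterwards, an initial fast decline at rate
  ``alpha`` of the effector fraction ``1 - fb`` and a slow terminal decline at
  rate ``beta`` of the persistent (memory) fraction ``fb``.

Two model variants are provided: a categorical covariate acting
multiplicatively on ``c_max`` (extramedullary disease), and expansion-rate
multipliers engaging at the first administration of tocilizumab and/or
corticosteroids during the expansion phase.  An ODE decomposition splits the
curve into effector and memory compartments.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate

__all__ = [
    "IndividualParams",
    "ComedicationSchedule",
    "EffectorMemoryTrajectory",
    "expansion_rate",
    "concentration",
    "concentration_with_covariate",
    "concentration_with_comedication",
    "effector_memory_decompose",
    "effector_memory_closed_form",
    "auc",
    "auc_trapezoid",
    "derived_constants",
    "trajectory_frame",
]

# exp() argument clip: keeps masked-out branch evaluations finite
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class IndividualParams:
    """One subject's structural parameters.

    Parameters
    ----------
    c_max : float
        Peak transgene concentration, copies/µg gDNA.
    t_max : float
        Time of the peak, days post-infusion.
    foldx : float
        Fold-expansion from the post-infusion baseline to the peak (> 1).
    fb : float
        Fraction of the peak contracting at the slow rate ``beta``, in (0, 1).
    alpha : float
        Initial (fast) contraction rate constant, 1/day.
    beta : float
        Terminal (slow) contraction rate constant, 1/day; ``beta < alpha``.
    """

    c_max: float
    t_max: float
    foldx: float
    fb: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("c_max", "t_max", "foldx", "fb", "alpha", "beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if self.foldx <= 1:
            raise ValueError(f"foldx must exceed 1, got {self.foldx!r}")
        if not 0 < self.fb < 1:
            raise ValueError(f"fb must lie in (0, 1), got {self.fb!r}")
        if self.beta >= self.alpha:
            raise ValueError(
                f"beta must be strictly smaller than alpha "
                f"(beta={self.beta!r}, alpha={self.alpha!r})"
            )

    @property
    def rho(self) -> float:
        """Exponential expansion rate ``ln(foldx)/t_max`` (1/day)."""
        return math.log(self.foldx) / self.t_max

    @property
    def baseline(self) -> float:
        """Model concentration immediately after infusion, ``c_max/foldx``."""
        return self.c_max / self.foldx


@dataclass(frozen=True)
class ComedicationSchedule:
    """First-administration times of CRS comedications and their rate effects.

    ``f1`` multiplies the expansion rate from the first tocilizumab dose
    onwards and ``f2`` from the first corticosteroid dose onwards; when both
    have been given the multipliers compound.  An absent drug (``None``) never
    engages its multiplier.
    """

    t_toci: float | None = None
    t_ster: float | None = None
    f1: float = 1.0
    f2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("t_toci", "t_ster"):
            v = getattr(self, name)
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative or None, got {v!r}")
        for name in ("f1", "f2"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive, got {v!r}")

    def events(self) -> list[tuple[float, float]]:
        """Engagement times and multipliers, in chronological order."""
        ev = []
        if self.t_toci is not None:
            ev.append((self.t_toci, self.f1))
        if self.t_ster is not None:
            ev.append((self.t_ster, self.f2))
        ev.sort(key=lambda e: e[0])
        return ev


@dataclass(frozen=True)
class EffectorMemoryTrajectory:
    """Effector (``y_alpha``) and memory (``y_beta``) compartment series."""

    times: np.ndarray
    y_alpha: np.ndarray
    y_beta: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.y_alpha + self.y_beta


def expansion_rate(foldx: float, t_max: float) -> float:
    """Expansion rate constant ``rho = ln(foldx)/t_max`` in 1/day."""
    if not (foldx > 0 and t_max > 0):
        raise ValueError(f"foldx and t_max must be positive, got {foldx!r}, {t_max!r}")
    return math.log(foldx) / t_max


def _effective_time(t, t1, m1, t2, m12):
    """Rate-multiplier-weighted expansion time ``∫0^t m(s) ds``.

    ``t1 <= t2`` are engagement times (``inf`` when absent), ``m1`` the
    multiplier active on ``[t1, t2)`` and ``m12`` the compounded multiplier
    active from ``t2`` on.
    """
    seg1 = np.minimum(t, t1)
    t1_finite = np.where(np.isinf(t1), 0.0, t1)
    width = np.where(np.isinf(t2), np.inf, t2 - t1_finite)
    seg2 = np.clip(t - t1, 0.0, width)
    seg3 = np.maximum(t - t2, 0.0)
    return seg1 + m1 * seg2 + m12 * seg3


def _conc_arrays(
    t,
    c_max,
    t_max,
    foldx,
    fb,
    alpha,
    beta,
    t1=np.inf,
    m1=1.0,
    t2=np.inf,
    m12=1.0,
    anchor_peak=True,
    smooth=0.0,
):
    """Vectorised piecewise concentration; all arguments broadcast.

    ``t1``/``t2`` are sorted comedication engagement times (``inf`` = never),
    ``m1``/``m12`` the rate multipliers on the corresponding segments.  With
    ``anchor_peak`` the contraction branch starts from ``c_max`` exactly as in
    the published piecewise formula even when rate multipliers prevented the
    expansion branch from attaining it; otherwise contraction starts from the
    attained end-of-expansion value (continuous variant).

    ``smooth`` > 0 replaces the hard branch switch by a logistic blend of the
    two branches on the log scale over a window of that width (days).  Both
    branches equal ``c_max`` at ``t_max``, so the blend deviates from the
    piecewise form only within a few window-widths of the peak; it exists for
    estimation code that needs the model differentiable in ``t_max``.
    """
    t = np.asarray(t, dtype=float)
    rho = np.log(foldx) / t_max
    e_t = _effective_time(t, t1, m1, t2, m12)
    log_up = np.log(c_max / foldx) + np.minimum(rho * e_t, _EXP_CLIP)
    if anchor_peak:
        log_c0 = np.log(c_max) + 0.0 * log_up
    else:
        e_peak = _effective_time(t_max, t1, m1, t2, m12)
        log_c0 = np.log(c_max / foldx) + np.minimum(rho * e_peak, _EXP_CLIP)
    tau = t - t_max
    log_down = log_c0 + np.log(
        (1.0 - fb) * np.exp(np.minimum(-alpha * tau, _EXP_CLIP))
        + fb * np.exp(np.minimum(-beta * tau, _EXP_CLIP))
    )
    if smooth > 0.0:
        from scipy.special import expit

        w = expit(tau / smooth)
        return np.exp(np.minimum((1.0 - w) * log_up + w * log_down, _EXP_CLIP))
    return np.exp(np.minimum(np.where(t < t_max, log_up, log_down), _EXP_CLIP))


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(~np.isfinite(t)):
        raise ValueError("times must be finite and non-negative (days post-infusion)")
    return t


def concentration(t, p: IndividualParams):
    """Transgene concentration at time(s) ``t`` days post-infusion.

    Piecewise closed form: ``(c_max/foldx)·exp(rho·t)`` before ``t_max`` and
    ``c_max·[(1-fb)·exp(-alpha·(t-t_max)) + fb·exp(-beta·(t-t_max))]`` from
    ``t_max`` on; the two branches meet at ``c_max``.
    """
    t_arr = _check_times(t)
    out = _conc_arrays(t_arr, p.c_max, p.t_max, p.foldx, p.fb, p.alpha, p.beta)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def concentration_with_covariate(t, p: IndividualParams, emm: bool, theta_emm: float):
    """Concentration with the extramedullary-disease multiplier on ``c_max``.

    For a subject with extramedullary involvement the typical peak is scaled
    by ``theta_emm`` (< 1 for an impaired peak); otherwise the base model
    applies unchanged.
    """
    if not theta_emm > 0:
        raise ValueError(f"theta_emm must be positive, got {theta_emm!r}")
    if emm:
        p = dataclasses.replace(p, c_max=p.c_max * theta_emm)
    return concentration(t, p)


def concentration_with_comedication(
    t,
    p: IndividualParams,
    sched: ComedicationSchedule,
    mode: str = "as-published",
    on_late_schedule: str = "warn",
):
    """Concentration with comedication expansion-rate multipliers.

    The expansion rate is ``rho`` before the first comedication, ``f·rho``
    between the two administrations (``f`` being the first drug's multiplier)
    and ``f1·f2·rho`` once both have been given, each segment continuing from
    the previous one.  Administrations are applied in chronological order, so
    steroids preceding tocilizumab are handled symmetrically.

    Parameters
    ----------
    mode : {"as-published", "continuous"}
        ``"as-published"`` anchors the contraction branch at ``c_max``
        regardless of the multipliers, which reproduces the piecewise formula
        as printed but leaves a jump at ``t_max`` whenever ``f1·f2 != 1``.
        ``"continuous"`` anchors contraction at the value actually attained at
        ``t_max``.
    on_late_schedule : {"warn", "error", "ignore"}
        Behaviour when an administration time falls at or after ``t_max``
        (such a dose cannot affect the expansion phase).
    """
    if mode not in ("as-published", "continuous"):
        raise ValueError(f"unknown mode {mode!r}")
    events = sched.events()
    if any(tt >= p.t_max for tt, _ in events):
        msg = (
            "comedication administered at or after t_max; it has no effect on "
            "the expansion phase"
        )
        if on_late_schedule == "error":
            raise ValueError(msg)
        if on_late_schedule == "warn":
            warnings.warn(msg, stacklevel=2)
    t_arr = _check_times(t)
    t1, m1 = events[0] if events else (np.inf, 1.0)
    if len(events) == 2:
        t2, m12 = events[1][0], events[0][1] * events[1][1]
    else:
        t2, m12 = np.inf, m1
    out = _conc_arrays(
        t_arr,
        p.c_max,
        p.t_max,
        p.foldx,
        p.fb,
        p.alpha,
        p.beta,
        t1=t1,
        m1=m1,
        t2=t2,
        m12=m12,
        anchor_peak=(mode == "as-published"),
    )
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def effector_memory_closed_form(p: IndividualParams, times) -> EffectorMemoryTrajectory:
    """Analytic solution of the effector/memory compartment system.

    Before ``t_max`` the whole population is effector; afterwards
    ``y_alpha(t) = c_max·exp(-alpha·tau)`` and
    ``y_beta(t) = fb·c_max·(exp(-beta·tau) - exp(-alpha·tau))`` with
    ``tau = t - t_max``, whose sum reproduces :func:`concentration`.
    """
    t = _check_times(times)
    tau = np.maximum(t - p.t_max, 0.0)
    pre = t <= p.t_max
    y_a = np.where(
        pre,
        p.baseline * np.exp(np.minimum(p.rho * np.minimum(t, p.t_max), _EXP_CLIP)),
        p.c_max * np.exp(-p.alpha * tau),
    )
    y_b = np.where(pre, 0.0, p.fb * p.c_max * (np.exp(-p.beta * tau) - np.exp(-p.alpha * tau)))
    return EffectorMemoryTrajectory(times=t, y_alpha=y_a, y_beta=y_b)


def effector_memory_decompose(
    p: IndividualParams, times, rtol: float = 1e-9, atol: float | None = None
) -> EffectorMemoryTrajectory:
    """Numerically integrate the effector/memory compartment ODEs.

    The effector compartment ``y_alpha`` grows exponentially at ``rho`` up to
    ``t_max`` (starting from ``c_max/foldx``) and declines at ``alpha``
    afterwards; the memory compartment ``y_beta`` is zero through ``t_max``
    and thereafter receives inflow ``fb·(alpha-beta)·y_alpha`` while declining
    at ``beta``.  The integration is split at ``t_max`` so the rate switch is
    never stepped over.
    """
    t = _check_times(times)
    if t.ndim != 1 or np.any(np.diff(t) < 0):
        raise ValueError("times must be a non-decreasing 1-D grid")
    if atol is None:
        atol = 1e-12 * p.c_max
    rho, tmax = p.rho, p.t_max

    def rhs_pre(_t, y):
        return [rho * y[0], 0.0]

    def rhs_post(_t, y):
        return [-p.alpha * y[0], p.fb * (p.alpha - p.beta) * y[0] - p.beta * y[1]]

    y_a = np.empty_like(t)
    y_b = np.empty_like(t)
    y0 = [p.baseline, 0.0]
    pre_mask = t <= tmax
    t_end = float(t[-1]) if t.size else tmax

    if np.any(pre_mask):
        sol_pre = integrate.solve_ivp(
            rhs_pre,
            (0.0, tmax),
            y0,
            t_eval=t[pre_mask],
            rtol=rtol,
            atol=atol,
            method="RK45",
        )
        if not sol_pre.success:
            raise RuntimeError(
                f"expansion-phase integration failed: {sol_pre.message} "
                f"(nfev={sol_pre.nfev}, last t={sol_pre.t[-1] if sol_pre.t.size else 0.0})"
            )
        y_a[pre_mask] = sol_pre.y[0]
        y_b[pre_mask] = 0.0

    if np.any(~pre_mask):
        # restart at t_max from the integrated expansion endpoint
        bridge = integrate.solve_ivp(
            rhs_pre, (0.0, tmax), y0, rtol=rtol, atol=atol, method="RK45"
        )
        if not bridge.success:
            raise RuntimeError(f"integration to t_max failed: {bridge.message}")
        y_tmax = [bridge.y[0, -1], 0.0]
        sol_post = integrate.solve_ivp(
            rhs_post,
            (tmax, t_end),
            y_tmax,
            t_eval=t[~pre_mask],
            rtol=rtol,
            atol=atol,
            method="RK45",
        )
        if not sol_post.success:
            raise RuntimeError(
                f"contraction-phase integration failed: {sol_post.message} "
                f"(nfev={sol_post.nfev})"
            )
        y_a[~pre_mask] = sol_post.y[0]
        y_b[~pre_mask] = np.maximum(sol_post.y[1], 0.0)
    return EffectorMemoryTrajectory(times=t, y_alpha=y_a, y_beta=y_b)


def _auc_closed_form(p: IndividualParams, t0: float, t1: float) -> float:
    """Analytic integral of the piecewise model over [t0, t1]."""
    total = 0.0
    a, b = max(t0, 0.0), min(t1, p.t_max)
    if b > a:  # expansion segment
        rho = p.rho
        if rho > 0:
            total += p.baseline * (math.exp(rho * b) - math.exp(rho * a)) / rho
        else:
            total += p.baseline * (b - a)
    a, b = max(t0, p.t_max), t1
    if b > a:  # contraction segment
        ta, tb = a - p.t_max, b - p.t_max
        if math.isclose(p.alpha, p.beta, rel_tol=1e-12):
            total += p.c_max * (math.exp(-p.alpha * ta) - math.exp(-p.alpha * tb)) / p.alpha
        else:
            total += p.c_max * (
                (1.0 - p.fb)
                * (math.exp(-p.alpha * ta) - math.exp(-p.alpha * tb))
                / p.alpha
                + p.fb * (math.exp(-p.beta * ta) - math.exp(-p.beta * tb)) / p.beta
            )
    return total


def auc_trapezoid(times, values, t0: float, t1: float) -> float:
    """Linear-trapezoid AUC of an observed series restricted to [t0, t1].

    Window edges inside the observed span are filled by linear interpolation;
    the series must bracket the window.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(t)
    t, y = t[order], y[order]
    if t.size < 2:
        raise ValueError("need at least two observations for a trapezoidal AUC")
    if t0 < t[0] or t1 > t[-1]:
        raise ValueError(f"observations do not cover [{t0}, {t1}]")
    inner = (t > t0) & (t < t1)
    tt = np.concatenate(([t0], t[inner], [t1]))
    yy = np.concatenate(([np.interp(t0, t, y)], y[inner], [np.interp(t1, t, y)]))
    return float(np.trapezoid(yy, tt))


def auc(
    p: IndividualParams | None,
    t0: float,
    t1: float,
    method: str = "closed_form",
    observations: tuple | None = None,
) -> float:
    """Area under the concentration curve over [t0, t1], copies·day/µg.

    ``method="closed_form"`` integrates the piecewise exponentials
    analytically from ``p``; ``method="trapezoid"`` applies the linear
    trapezoid rule to an observed ``(times, values)`` series.
    """
    if not (0 <= t0 < t1):
        raise ValueError(f"need 0 <= t0 < t1, got ({t0!r}, {t1!r})")
    if method == "closed_form":
        if p is None:
            raise ValueError("closed_form AUC requires individual parameters")
        return _auc_closed_form(p, t0, t1)
    if method == "trapezoid":
        if observations is None:
            raise ValueError("trapezoid AUC requires an (times, values) series")
        return auc_trapezoid(observations[0], observations[1], t0, t1)
    raise ValueError(f"unknown AUC method {method!r}")


def derived_constants(p: IndividualParams) -> dict:
    """Doubling time ``ln2/rho`` and half-lives ``ln2/alpha``, ``ln2/beta`` (days)."""
    ln2 = math.log(2.0)
    return {
        "doubling_time": ln2 / p.rho,
        "half_life_alpha": ln2 / p.alpha,
        "half_life_beta": ln2 / p.beta,
    }


def trajectory_frame(traj: EffectorMemoryTrajectory, subject_id) -> "pd.DataFrame":
    """Tidy long-format export (subject, time_days, value, compartment)."""
    import pandas as pd

    n = traj.times.size
    return pd.DataFrame(
        {
            "subject": np.repeat(subject_id, 2 * n),
            "time_days": np.concatenate([traj.times, traj.times]),
            "value": np.concatenate([traj.y_alpha, traj.y_beta]),
            "compartment": np.repeat(["effector", "memory"], n),
        }
    )
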