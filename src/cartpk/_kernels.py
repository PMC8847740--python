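"""JIT-compiled evaluation kernels for the estimation engine.

The inner Laplace machinery evaluates the structural model and the
observation -2 log-likelihood thousands of times on small (n_subjects x
n_obs) arrays, where numpy call overhead dominates.  These numba kernels
reproduce the vectorised numpy computations exactly (same guards, same
branch-smoothing blend); :mod:`cartpk.nlme` falls back to the numpy path
when numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is an optional accelerator
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


_EXP_CLIP = 700.0
_SQRT2 = math.sqrt(2.0)
_LN2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _log_ndtr(z: float) -> float:
    """Stable log of the standard normal CDF."""
    if z > -8.0:
        return math.log(0.5 * math.erfc(-z / _SQRT2))
    # asymptotic expansion in the far-left tail
    z2 = z * z
    return -0.5 * z2 - math.log(-z) - 0.5 * _LN2PI + math.log1p(-1.0 / z2 + 3.0 / (z2 * z2))


@njit(cache=True)
def _conc_point(
    t, c_max, t_max, foldx, fb, alpha, beta, t1, m1, t2, m12, anchor_peak, smooth
):
    rho = math.log(foldx) / t_max
    # rate-multiplier-weighted expansion time
    seg1 = t if t < t1 else t1
    if t > t1:
        width = t2 - t1
        d = t - t1
        seg2 = d if d < width else width
    else:
        seg2 = 0.0
    seg3 = t - t2 if t > t2 else 0.0
    e_t = seg1 + m1 * seg2 + m12 * seg3
    log_up = math.log(c_max / foldx) + min(rho * e_t, _EXP_CLIP)
    if anchor_peak:
        log_c0 = math.log(c_max)
    else:
        s1 = t_max if t_max < t1 else t1
        if t_max > t1:
            width = t2 - t1
            d = t_max - t1
            s2 = d if d < width else width
        else:
            s2 = 0.0
        s3 = t_max - t2 if t_max > t2 else 0.0
        log_c0 = math.log(c_max / foldx) + min(rho * (s1 + m1 * s2 + m12 * s3), _EXP_CLIP)
    tau = t - t_max
    a1 = min(-alpha * tau, _EXP_CLIP)
    a2 = min(-beta * tau, _EXP_CLIP)
    log_down = log_c0 + math.log((1.0 - fb) * math.exp(a1) + fb * math.exp(a2))
    if smooth > 0.0:
        x = tau / smooth
        if x > 36.0:
            w = 1.0
        elif x < -36.0:
            w = 0.0
        else:
            w = 1.0 / (1.0 + math.exp(-x))
        return math.exp(min((1.0 - w) * log_up + w * log_down, _EXP_CLIP))
    if t < t_max:
        return math.exp(min(log_up, _EXP_CLIP))
    return math.exp(min(log_down, _EXP_CLIP))


@njit(cache=True)
def conc_batch(t, P, t1, m1, t2, m12, anchor_peak, smooth):
    n, m = t.shape
    out = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            out[i, j] = _conc_point(
                t[i, j],
                P[i, 0],
                P[i, 1],
                P[i, 2],
                P[i, 3],
                P[i, 4],
                P[i, 5],
                t1[i],
                m1[i],
                t2[i],
                m12[i],
                anchor_peak,
                smooth,
            )
    return out


@njit(cache=True)
def obs_neg2ll_batch(
    t, y, quant, blq, loq, P, t1, m1, t2, m12, anchor_peak, smooth, sp, sa, log_scale
):
    """Per-subject observation -2 log-likelihood (no eta prior term)."""
    n, m = t.shape
    out = np.zeros(n)
    for i in range(n):
        acc = 0.0
        for j in range(m):
            if not (quant[i, j] or blq[i, j]):
                continue
            f = _conc_point(
                t[i, j],
                P[i, 0],
                P[i, 1],
                P[i, 2],
                P[i, 3],
                P[i, 4],
                P[i, 5],
                t1[i],
                m1[i],
                t2[i],
                m12[i],
                anchor_peak,
                smooth,
            )
            if log_scale:
                fl = f if f > 1e-300 else 1e-300
                v = sp * sp + (sa / fl) * (sa / fl)
                mu = math.log(fl)
                if quant[i, j]:
                    yy = y[i, j] if y[i, j] > 1e-300 else 1e-300
                    r = math.log(yy) - mu
                    acc += math.log(v) + _LN2PI + r * r / v
                else:
                    z = (math.log(loq[i, j]) - mu) / math.sqrt(v)
                    acc += -2.0 * _log_ndtr(z)
            else:
                v = (sp * f) * (sp * f) + sa * sa
                if quant[i, j]:
                    r = y[i, j] - f
                    acc += math.log(v) + _LN2PI + r * r / v
                else:
                    z = (loq[i, j] - f) / math.sqrt(v)
                    acc += -2.0 * _log_ndtr(z)
        out[i] = acc if math.isfinite(acc) else 1e12
    return out
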