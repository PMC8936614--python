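"""Wiener first-passage-time density for the two-boundary diffusion.

The density of absorption at the *lower* boundary for a diffusion with unit
noise, drift ``v``, boundary separation ``a`` and relative start ``w`` is
evaluated through the normalized density ``f(t* | 0, 1, w)`` with
``t* = t / a**2``, using whichever of the small-time and large-time series
expansions needs fewer terms for truncation error <= ``eps``:

    small-time:  (2*pi*t*^3)^(-1/2) * sum_k (w + 2k) * exp(-(w + 2k)^2 / (2 t*))
    large-time:  pi * sum_k k * exp(-k^2 pi^2 t* / 2) * sin(k pi w)

then rescaled by ``a**-2 * exp(-v a w - v^2 t / 2)``.  The upper-boundary
density follows from the reflection ``(v, w) -> (-v, 1 - w)``.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["wfpt_logpdf", "wfpt_pdf", "absorption_prob_upper"]

_NEG_INF = -np.inf


@njit(cache=True)
def _std_fpt_density(tt: float, w: float, eps: float) -> float:
    """Normalized lower-boundary density f(tt | v=0, a=1, w)."""
    if tt <= 0.0:
        return 0.0
    # required number of terms for each expansion (Navarro-Fuss bounds)
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * eps < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * eps * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    if math.pi * tt * eps < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * eps) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = (K - 1) // 2 + (K - 1) % 2
        acc = 0.0
        for k in range(lo, hi + 1):
            u = w + 2.0 * k
            acc += u * math.exp(-u * u / (2.0 * tt))
        p = acc / math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p = acc * math.pi
    if p < 0.0:
        p = 0.0
    return p


@njit(cache=True)
def _wfpt_logpdf_scalar(t: float, v: float, a: float, w: float, eps: float) -> float:
    if t <= 0.0:
        return _NEG_INF
    tt = t / (a * a)
    p = _std_fpt_density(tt, w, eps)
    if p <= 0.0:
        return _NEG_INF
    return math.log(p) - v * a * w - v * v * t / 2.0 - 2.0 * math.log(a)


@njit(cache=True)
def _wfpt_logpdf_arr(t, v, a, w, eps, out):
    for i in range(t.shape[0]):
        out[i] = _wfpt_logpdf_scalar(t[i], v, a, w, eps)


def _validate(boundary: float, w: float, eps: float) -> None:
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    if not 0 < w < 1:
        raise ValueError("starting-point fraction w must lie in (0, 1)")
    if not 0 < eps <= 1e-4:
        raise ValueError("eps must lie in (0, 1e-4]")


def wfpt_logpdf(t, drift: float, boundary: float, w: float = 0.5, eps: float = 1e-7):
    """Log density of lower-boundary absorption at decision time ``t``.

    ``t <= 0`` yields ``-inf`` rather than raising, so likelihood code can
    reject impossible data (e.g. rt below the nondecision time) gracefully.
    Accepts a scalar or an array of times.
    """
    _validate(boundary, w, eps)
    if not np.isfinite(drift):
        raise ValueError("drift must be finite")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    _wfpt_logpdf_arr(t_arr, float(drift), float(boundary), float(w), float(eps), out)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def wfpt_pdf(t, drift: float, boundary: float, w: float = 0.5, eps: float = 1e-7,
             boundary_side: str = "lower"):
    """Density of absorption at ``boundary_side`` at decision time ``t``."""
    if boundary_side == "lower":
        return np.exp(wfpt_logpdf(t, drift, boundary, w, eps))
    if boundary_side == "upper":
        return np.exp(wfpt_logpdf(t, -drift, boundary, 1.0 - w, eps))
    raise ValueError("boundary_side must be 'lower' or 'upper'")


def absorption_prob_upper(drift: float, boundary: float, w: float = 0.5) -> float:
    """Closed-form probability of upper-boundary absorption (unit noise)."""
    _validate(boundary, w, 1e-7)
    if drift == 0.0:
        return float(w)
    z = w * boundary
    return float((1.0 - math.exp(-2.0 * drift * z)) / (1.0 - math.exp(-2.0 * drift * boundary)))
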