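"""Euler-Maruyama simulation of the two-boundary diffusion (unit noise)."""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _simulate_paths(n: int, drift: float, boundary: float, w: float, ndt: float,
                    dt: float, t_max: float, seed: int):
    np.random.seed(seed)
    choices = np.empty(n, dtype=np.int64)
    rts = np.empty(n, dtype=np.float64)
    sq = math.sqrt(dt)
    for i in range(n):
        x = w * boundary
        t = 0.0
        while True:
            x += drift * dt + sq * np.random.standard_normal()
            t += dt
            if x >= boundary:
                choices[i] = 1
                break
            if x <= 0.0:
                choices[i] = 0
                break
            if t >= t_max:
                # unabsorbed at the cap: report the nearer boundary
                choices[i] = 1 if x >= w * boundary else 0
                break
        rts[i] = t + ndt
    return choices, rts


@njit(cache=True)
def _simulate_paths_per_trial(drifts, boundaries, ndts, w: float, dt: float,
                              t_max: float, seed: int):
    np.random.seed(seed)
    n = drifts.shape[0]
    choices = np.empty(n, dtype=np.int64)
    rts = np.empty(n, dtype=np.float64)
    decision_times = np.empty(n, dtype=np.float64)
    sq = math.sqrt(dt)
    for i in range(n):
        a = boundaries[i]
        v = drifts[i]
        x = w * a
        t = 0.0
        while True:
            x += v * dt + sq * np.random.standard_normal()
            t += dt
            if x >= a:
                choices[i] = 1
                break
            if x <= 0.0:
                choices[i] = 0
                break
            if t >= t_max:
                choices[i] = 1 if x >= w * a else 0
                break
        decision_times[i] = t
        rts[i] = t + ndts[i]
    return choices, decision_times, rts


def simulate_paths_per_trial(drifts, boundaries, ndts, w: float, seed: int,
                             dt: float = 1e-3, t_max: float = 30.0):
    """Vectorized-over-trials first-passage simulation with per-trial params.

    Returns (choices, decision_times, rts); choice 1 = upper boundary.
    """
    drifts = np.ascontiguousarray(drifts, dtype=float)
    boundaries = np.ascontiguousarray(boundaries, dtype=float)
    ndts = np.ascontiguousarray(ndts, dtype=float)
    if not (drifts.shape == boundaries.shape == ndts.shape):
        raise ValueError("parameter arrays must share a shape")
    if np.any(boundaries <= 0):
        raise ValueError("boundaries must be positive")
    if not np.all(np.isfinite(drifts)):
        raise ValueError("drifts must be finite")
    return _simulate_paths_per_trial(drifts, boundaries, ndts, float(w),
                                     float(dt), float(t_max),
                                     int(seed) & 0xFFFFFFFF)


def simulate_paths(n: int, drift: float, boundary: float, w: float, ndt: float,
                   seed: int, dt: float = 5e-4, t_max: float = 30.0):
    """Simulate ``n`` first-passage trials; returns (choices, rts).

    choice 1 = upper boundary, 0 = lower; rt includes the nondecision offset.
    Paths still unabsorbed at ``t_max`` are truncated there (rare under
    sensible parameters) and assigned the nearer boundary.
    """
    if boundary <= 0:
        raise ValueError("boundary must be positive")
    if not 0 < w < 1:
        raise ValueError("w must lie in (0, 1)")
    if not np.isfinite(drift):
        raise ValueError("drift must be finite")
    if ndt < 0:
        raise ValueError("ndt must be nonnegative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return _simulate_paths(int(n), float(drift), float(boundary), float(w),
                           float(ndt), float(dt), float(t_max), int(seed) & 0xFFFFFFFF)
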