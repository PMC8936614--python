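"""Kinematic features, trial quality control and psychometric summaries.

Operates on 1-D finger-position traces: velocity by finite differences,
movement parameters (mean speed, midline crossings, low-side dwell time),
response-time trial filters, and a cumulative-Gaussian psychometric fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "PositionTrace",
    "MovementParams",
    "PsychometricFit",
    "compute_velocity",
    "movement_parameters",
    "qc_filter_trials",
    "fit_psychometric",
    "RT_MIN",
    "RT_MAX",
]

# trials with rt outside [RT_MIN, RT_MAX] seconds are rejected (closed interval:
# exact-boundary trials are kept)
RT_MIN = 0.3
RT_MAX = 10.0


@dataclass
class PositionTrace:
    """Finger position over one trial; ``x`` in mm, sampled at ``fs`` Hz."""

    x: np.ndarray
    fs: float
    y: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1 or self.x.size < 2:
            raise ValueError("position trace needs >= 2 samples")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("position trace contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
            if self.y.shape != self.x.shape:
                raise ValueError("y must match x in length")

    @property
    def duration(self) -> float:
        return self.x.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.fs


@dataclass
class MovementParams:
    v_m: float      # mean absolute x-velocity, mm/s
    n_cr: int       # midline crossings
    t_low: float    # dwell time on the low-amplitude side, s


@dataclass
class PsychometricFit:
    pse: float      # point of subjective equality (fitted mean)
    slope: float    # d P(nonreference) / d diff at the PSE
    mu: float
    sigma: float
    n_trials: int = 0
    converged: bool = True


def compute_velocity(trace: PositionTrace) -> np.ndarray:
    """Velocity in mm/s: central differences interior, one-sided at the ends."""
    return np.gradient(trace.x, 1.0 / trace.fs)


def _crossings(x: np.ndarray, midline: float) -> int:
    d = x - midline
    sign = np.sign(d)
    # samples exactly on the midline inherit the previous side
    on = sign == 0
    if on.all():
        warnings.warn("trace lies entirely on the midline; n_cr = 0", stacklevel=3)
        return 0
    if on.any():
        idx = np.where(~on, np.arange(x.size), -1)
        np.maximum.accumulate(idx, out=idx)
        first = np.argmax(~on)
        idx[idx < 0] = first
        sign = sign[idx]
    return int(np.count_nonzero(np.diff(sign) != 0))


def movement_parameters(trace: PositionTrace, midline: float,
                        low_side: str) -> MovementParams:
    """Mean speed, midline crossings, and dwell time on the low-amplitude side.

    ``low_side`` is "L" or "R" and marks which subspace held the
    lower-amplitude stimulus on this trial.  Only the x channel is used.
    """
    if low_side not in ("L", "R"):
        raise ValueError("low_side must be 'L' or 'R'")
    v = compute_velocity(trace)
    v_m = float(np.mean(np.abs(v)))
    n_cr = _crossings(trace.x, midline)
    if low_side == "L":
        on_low = trace.x < midline
    else:
        on_low = trace.x > midline
    t_low = float(np.count_nonzero(on_low) / trace.fs)
    return MovementParams(v_m=v_m, n_cr=n_cr, t_low=t_low)


def qc_filter_trials(table: pd.DataFrame,
                     rt_min: float = RT_MIN,
                     rt_max: float = RT_MAX) -> tuple[pd.DataFrame, dict]:
    """Keep trials with rt in the closed interval [rt_min, rt_max] seconds.

    Returns the filtered table and a report with the rejected trial index
    labels and the fraction rejected.
    """
    if len(table) == 0:
        raise ValueError("behavior table is empty")
    if "rt" not in table.columns:
        raise ValueError("behavior table lacks an 'rt' column")
    keep = (table["rt"] >= rt_min) & (table["rt"] <= rt_max)
    rejected = table.index[~keep].tolist()
    report = {
        "n_total": int(len(table)),
        "n_rejected": int(len(rejected)),
        "rejected_ids": rejected,
        "fraction_rejected": float(len(rejected) / len(table)),
        "rt_min": rt_min,
        "rt_max": rt_max,
    }
    return table.loc[keep].copy(), report


def _psychometric_nll(params: np.ndarray, diffs: np.ndarray, choices: np.ndarray) -> float:
    mu, log_sigma = params
    sigma = np.exp(log_sigma)
    p = stats.norm.cdf((diffs - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -float(np.sum(choices * np.log(p) + (1 - choices) * np.log(1 - p)))


def fit_psychometric(choices, diffs) -> PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit of nonreference-choice data.

    ``choices`` are binary indicators of choosing the nonreference stimulus,
    ``diffs`` the signed amplitude differences.  The PSE is the fitted mean;
    the slope at the PSE is ``phi(0) / sigma``.  No lapse-rate parameter.
    """
    choices = np.asarray(choices, dtype=float)
    diffs = np.asarray(diffs, dtype=float)
    if choices.shape != diffs.shape or choices.ndim != 1:
        raise ValueError("choices and diffs must be matching 1-D arrays")
    if not np.isin(choices, (0.0, 1.0)).all():
        raise ValueError("choices must be binary")
    if np.unique(diffs).size < 2:
        raise ValueError("need >= 2 distinct difference levels")
    if choices.min() == choices.max():
        raise ValueError("all choices identical; psychometric fit not identifiable")

    spread = max(np.std(diffs), 1e-3)
    best = None
    for sigma0 in (spread, spread / 4, spread * 4):
        res = optimize.minimize(
            _psychometric_nll, x0=np.array([np.mean(diffs), np.log(sigma0)]),
            args=(diffs, choices), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    sigma = float(np.exp(log_sigma))
    slope = float(stats.norm.pdf(0.0) / sigma)
    return PsychometricFit(pse=float(mu), slope=slope, mu=float(mu), sigma=sigma,
                           n_trials=int(choices.size), converged=bool(best.success))
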