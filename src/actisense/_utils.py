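"""Shared low-level helpers: seeding, sample shifting, lagged kernels."""

from __future__ import annotations

import numpy as np


def spawn_rng(seed: int, *key: int) -> np.random.Generator:
    """Derive an independent, reproducible substream from a root seed.

    ``key`` identifies the consumer (stage index, participant index, trial
    index, ...) so that stages can be rerun in isolation without seed
    collisions.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, key))))


def shift(x: np.ndarray, k: int) -> np.ndarray:
    """Return ``y`` with ``y[t] = x[t - k]``, zero-padded at the edges."""
    x = np.asarray(x)
    y = np.zeros_like(x, dtype=float)
    n = x.shape[0]
    if k >= n or -k >= n:
        return y
    if k >= 0:
        y[k:] = x[: n - k]
    else:
        y[: n + k] = x[-k:]
    return y


def lag_samples(lag_min_ms: float, lag_max_ms: float, fs: float) -> np.ndarray:
    """Integer sample lags covering [lag_min_ms, lag_max_ms] at rate fs."""
    lo = int(round(lag_min_ms * fs / 1000.0))
    hi = int(round(lag_max_ms * fs / 1000.0))
    if lo >= hi:
        raise ValueError("lag window is empty after quantization to samples")
    return np.arange(lo, hi + 1)


def lagged_matrix(x: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Columns are zero-padded shifted copies of ``x``: col j = x[t - lags[j]]."""
    x = np.asarray(x, dtype=float)
    return np.column_stack([shift(x, int(k)) for k in lags])


def apply_lag_kernel(x: np.ndarray, pattern: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Mix a 1-D signal through per-channel lag kernels.

    Returns an (n_samples, n_channels) array with
    ``out[t, i] = sum_j pattern[i, j] * x[t - lags[j]]`` (zero-padded edges).
    ``pattern`` has shape (n_channels, n_lags).
    """
    pattern = np.asarray(pattern, dtype=float)
    if pattern.ndim != 2 or pattern.shape[1] != len(lags):
        raise ValueError("pattern must be (n_channels, n_lags)")
    return lagged_matrix(x, lags) @ pattern.T
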