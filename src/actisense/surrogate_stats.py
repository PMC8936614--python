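"""Phase-randomization surrogates and empirical nulls for decoding accuracy.

Surrogates keep each channel's amplitude spectrum bin-by-bin (hence its
autocorrelation) while replacing the phases of positive frequencies with
i.i.d. uniform draws, destroying the temporal relation to the kinematics.
The decode-and-score statistic is recomputed on each surrogate to build a
null distribution, and p-values use the plus-one rule
``p = (1 + #{null >= observed}) / (1 + n_surrogates)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._utils import spawn_rng
from .dataset import EEGTrace
from .trf_decoding import LagSpec, score_single_trials, DEFAULT_LAMBDA

__all__ = ["SurrogateNull", "phase_randomize", "null_r2_distribution"]


@dataclass
class SurrogateNull:
    n_surrogates: int
    null_r2: np.ndarray
    observed_r2: float
    p: float


def phase_randomize(signal: np.ndarray, seed: int) -> np.ndarray:
    """Surrogate with the original magnitude spectrum and random phases.

    DC and (for even lengths) Nyquist bins keep their phase so the output is
    exactly real.  Columns of a 2-D input are randomized independently.
    """
    x = np.asarray(signal, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signal must be finite")
    if x.shape[0] < 4:
        raise ValueError("signal too short to phase-randomize (need >= 4 samples)")
    rng = spawn_rng(seed, 0x5A11)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    spec = np.fft.rfft(x, axis=0)
    n_bins = spec.shape[0]
    # randomizable bins: positive frequencies excluding DC and (even n) Nyquist
    hi = n_bins - 1 if n % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(hi - 1, x.shape[1]))
    rot = np.ones_like(spec)
    rot[1:hi] = np.exp(1j * phases)
    out = np.fft.irfft(spec * rot, n=n, axis=0)
    return out[:, 0] if squeeze else out


class _SurrogateTrial:
    """Duck-typed trial shim: surrogate EEG with the original kinematics."""

    __slots__ = ("eeg", "velocity", "trial")

    def __init__(self, eeg: EEGTrace, velocity: np.ndarray, trial) -> None:
        self.eeg = eeg
        self.velocity = velocity
        self.trial = trial


def _surrogate_trials(trials, seed: int, shared_phases: bool):
    out = []
    for k, t in enumerate(trials):
        if shared_phases:
            data = phase_randomize(t.eeg.data, seed=(seed * 1000003 + k) & 0x7FFFFFFF)
        else:
            cols = [phase_randomize(t.eeg.data[:, i],
                                    seed=(seed * 1000003 + k * 4093 + i) & 0x7FFFFFFF)
                    for i in range(t.eeg.n_channels)]
            data = np.column_stack(cols)
        eeg = EEGTrace(data=data, fs=t.eeg.fs, labels=list(t.eeg.labels))
        out.append(_SurrogateTrial(eeg, np.asarray(t.velocity, dtype=float),
                                   getattr(t, "trial", k)))
    return out


def _mean_r2(trials, lag_spec: LagSpec, lam: float, refit: bool,
             observed_model=None, seed: int = 0) -> float:
    if refit:
        score = score_single_trials(trials, lag_spec, lam, seed=seed)
        return float(np.nanmean(score.r2))
    from .trf_decoding import predict_velocity, _r2
    vals = [_r2(predict_velocity(observed_model, t.eeg), np.asarray(t.velocity))
            for t in trials]
    return float(np.nanmean(vals))


def null_r2_distribution(trials, lag_spec: LagSpec, n: int = 1000, seed: int = 0,
                         lam: float = DEFAULT_LAMBDA, refit: bool = True,
                         shared_phases: bool = False) -> SurrogateNull:
    """Null distribution of the mean cross-fitted r^2 under phase surrogates.

    Each surrogate phase-randomizes every EEG channel independently (set
    ``shared_phases=True`` to preserve cross-spectra instead) and repeats the
    full decode-and-score procedure (``refit=False`` re-scores the observed
    decoder instead of refitting, a weaker but faster null).
    """
    if n < 1:
        raise ValueError("need at least one surrogate")
    if n < 100:
        warnings.warn("fewer than 100 surrogates: tail estimate is unstable",
                      stacklevel=2)
    observed_model = None
    if not refit:
        from .trf_decoding import train_decoder
        observed_model = train_decoder(trials, lag_spec, lam)
    observed = _mean_r2(trials, lag_spec, lam, refit, observed_model, seed=seed)
    null = np.empty(n)
    for b in range(n):
        sur = _surrogate_trials(trials, seed=int(spawn_rng(seed, 0xB00, b).integers(2**31)),
                                shared_phases=shared_phases)
        null[b] = _mean_r2(sur, lag_spec, lam, refit, observed_model, seed=seed)
    p = float((1 + np.count_nonzero(null >= observed)) / (1 + n))
    return SurrogateNull(n_surrogates=n, null_r2=null, observed_r2=observed, p=p)
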