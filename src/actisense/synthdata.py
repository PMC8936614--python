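"""Seeded synthetic datasets with the statistical structure the pipeline assumes.

Three generators compose into full datasets:

* ``simulate_trajectory`` — free left/right scanning of a bounded workspace,
  modeled as a side-switching telegraph process modulating a bounded
  oscillatory scan plus smoothed broadband jitter;
* ``simulate_eeg`` — multichannel EEG as a lagged linear mixture of finger
  velocity plus Gaussian noise at a configurable signal-to-noise ratio;
* ``simulate_behavior`` — choice and response time from an Euler-Maruyama
  two-boundary diffusion whose drift is modulated by the trial's latent
  neural-coupling strength times stimulus difference and whose nondecision
  time is modulated by the realized movement parameters.

Every generated artifact is reproducible from the config seed, and the
ground truth (mixing pattern, latent couplings, true decision parameters) is
returned alongside so downstream recovery tests have an oracle.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._diffusion import simulate_paths, simulate_paths_per_trial
from ._utils import apply_lag_kernel, lag_samples, spawn_rng
from .dataset import Dataset, EEGTrace, TrialRecording
from .kinematics import PositionTrace, movement_parameters
from .montage import channel_labels

__all__ = [
    "TrueDDMParams",
    "SimConfig",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_eeg",
    "simulate_behavior",
    "default_forward_pattern",
    "generate_behavior_table",
    "generate_dataset",
]

_STAGE_TRAJ, _STAGE_EEG, _STAGE_DDM, _STAGE_MISC = 1, 2, 3, 4


def _per_condition(value, conditions) -> dict:
    if isinstance(value, dict):
        missing = [c for c in conditions if c not in value]
        if missing:
            raise ValueError(f"missing per-condition values for {missing}")
        return {c: float(value[c]) for c in conditions}
    return {c: float(value) for c in conditions}


@dataclass
class TrueDDMParams:
    """Generating decision-model parameters, per condition.

    drift = gamma0 + gamma1 * coupling * s; nondecision time =
    beta0 + beta_sw * n_cr + beta_exp * t_low; boundary = alpha; the starting
    point is fixed at the midpoint (w = 0.5).  ``participant_sd`` gives the
    between-participant standard deviation of each parameter family.
    """

    gamma0: dict | float = 0.8
    gamma1: dict | float = field(default_factory=lambda: {"V": 1.5, "H": 1.5, "VH": 2.5})
    alpha: dict | float = 2.0
    beta0: dict | float = 1.0
    beta_sw: dict | float = 0.06
    beta_exp: dict | float = 0.3
    w: float = 0.5
    participant_sd: dict = field(default_factory=lambda: {
        "gamma0": 0.15, "gamma1": 0.3, "alpha": 0.15,
        "beta0": 0.08, "beta_sw": 0.01, "beta_exp": 0.04,
    })

    def resolve(self, conditions) -> dict:
        out = {}
        for name in ("gamma0", "gamma1", "alpha", "beta0", "beta_sw", "beta_exp"):
            out[name] = _per_condition(getattr(self, name), conditions)
        return out

    def validate(self, conditions) -> None:
        if self.w != 0.5:
            raise ValueError("starting-point fraction w must be exactly 0.5")
        r = self.resolve(conditions)
        for c in conditions:
            if r["alpha"][c] <= 0:
                raise ValueError("alpha must be positive")
            if r["beta0"][c] <= 0:
                raise ValueError("beta0 must be positive")


@dataclass
class SimConfig:
    n_participants: int = 12
    n_trials_per_cell: int = 20
    conditions: list = field(default_factory=lambda: ["V", "H", "VH"])
    amplitude_levels: list = field(default_factory=lambda: [0.5, 0.75, 0.9, 1.1, 1.25, 1.5])
    reference_amplitude: float = 1.0
    fs: float = 100.0
    workspace_x: tuple = (0.0, 110.0)
    midline_x: float = 55.0
    n_channels: int = 16
    coupling_snr: dict | float = field(default_factory=lambda: {"V": 0.5, "H": 0.5, "VH": 1.0})
    true_ddm: TrueDDMParams = field(default_factory=TrueDDMParams)
    seed: int = 0
    # trajectory-generator knobs (uncalibrated; see module docstring)
    switch_rate: float = 0.6        # mean side switches per second
    scan_hz: float = 1.5            # oscillatory scan frequency
    scan_amp: float = 12.0          # mm, pre-squashing scan amplitude
    jitter_sd: float = 8.0          # mm, pre-squashing broadband jitter
    jitter_smooth_ms: float = 30.0  # moving-average window for the jitter
    # EEG lag window of the generative mixing kernel
    lag_min_ms: float = -200.0
    lag_max_ms: float = 400.0
    # latent per-trial coupling strength ~ Beta(a, b) * scale  (an r^2-like
    # quantity, so its support must stay inside [0, 1])
    coupling_beta: tuple = (2.0, 2.0)
    coupling_scale: float = 0.4
    ddm_dt: float = 5e-4            # Euler-Maruyama step

    def __post_init__(self) -> None:
        if isinstance(self.true_ddm, dict):
            self.true_ddm = TrueDDMParams(**self.true_ddm)
        self.workspace_x = tuple(float(v) for v in self.workspace_x)
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_trials_per_cell < 1:
            raise ValueError("n_trials_per_cell must be >= 1")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        lo, hi = self.workspace_x
        if not lo < self.midline_x < hi:
            raise ValueError("midline_x must lie strictly inside workspace_x")
        if list(self.amplitude_levels) != sorted(self.amplitude_levels):
            raise ValueError("amplitude_levels must be sorted")
        if self.reference_amplitude in self.amplitude_levels:
            raise ValueError("reference amplitude must be excluded from levels")
        snr = _per_condition(self.coupling_snr, self.conditions)
        if any(v < 0 for v in snr.values()):
            raise ValueError("coupling_snr values must be >= 0")
        if "VH" in snr and {"V", "H"} <= set(snr):
            if snr["VH"] < max(snr["V"], snr["H"]):
                raise ValueError("default configs require coupling_snr[VH] >= max(V, H)")
        if not 0 < self.coupling_scale <= 1:
            raise ValueError("coupling_scale must lie in (0, 1]")
        self.true_ddm.validate(self.conditions)

    @property
    def snr_by_condition(self) -> dict:
        return _per_condition(self.coupling_snr, self.conditions)

    @property
    def stimulus_differences(self) -> list:
        return sorted({round(abs(a - self.reference_amplitude), 10)
                       for a in self.amplitude_levels})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(asdict(self)), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class GroundTruth:
    """Everything needed to verify recovery of generated structure."""

    seed: int
    true_ddm: TrueDDMParams
    lags: np.ndarray | None = None
    forward_pattern: np.ndarray | None = None   # channels x lags mixing kernel
    participant_params: pd.DataFrame | None = None
    latent_coupling: np.ndarray | None = None   # aligned with the trial table
    true_drift: np.ndarray | None = None        # generative per-trial drift

    def __post_init__(self) -> None:
        if self.forward_pattern is not None and not np.all(np.isfinite(self.forward_pattern)):
            raise ValueError("forward pattern must be finite")


# ---------------------------------------------------------------------------
# trajectory
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    if win <= 1:
        return x
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def simulate_trajectory(cfg: SimConfig, duration: float, seed: int,
                        switch_rate: float | None = None) -> PositionTrace:
    """One trial's 1-D scanning trajectory, sampled at ``cfg.fs``.

    A two-state Markov side process (mean rate ``switch_rate`` per second)
    sets which half of the workspace is being explored; within a side the
    finger oscillates and jitters, squashed through a tanh so it can never
    stray across the midline without a side switch.
    """
    fs = cfg.fs
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("degenerate trial: duration shorter than two sample periods")
    rate = cfg.switch_rate if switch_rate is None else float(switch_rate)
    if rate < 0:
        raise ValueError("switch rate must be >= 0")
    rng = spawn_rng(seed, _STAGE_TRAJ)
    t = np.arange(n) / fs

    # telegraph side process
    side = np.zeros(n, dtype=int)
    cur = int(rng.integers(2))
    if rate > 0:
        pos = 0.0
        idx = 0
        while pos < duration:
            hold = rng.exponential(1.0 / rate)
            nxt = min(n, int(round((pos + hold) * fs)))
            side[idx:nxt] = cur
            cur = 1 - cur
            pos += hold
            idx = nxt
        if idx < n:
            side[idx:] = cur
    else:
        side[:] = cur

    lo, hi = cfg.workspace_x
    mid = cfg.midline_x
    centers = np.array([(lo + mid) / 2.0, (mid + hi) / 2.0])
    halfw = np.array([(mid - lo) / 2.0, (hi - mid) / 2.0])
    raw = centers[side]
    # exponential smoothing of the side target (time constant ~120 ms)
    alpha = min(1.0, (1.0 / fs) / 0.12)
    base = np.empty(n)
    acc = raw[0]
    for i in range(n):
        acc += alpha * (raw[i] - acc)
        base[i] = acc

    phase = rng.uniform(0, 2 * np.pi)
    # per-trial frequency jitter keeps the scan oscillation incoherent across
    # trials (its autocorrelation would otherwise span the whole lag window)
    f_scan = cfg.scan_hz * rng.uniform(0.7, 1.3)
    scan = cfg.scan_amp * np.sin(2 * np.pi * f_scan * t + phase)
    win = max(1, int(round(cfg.jitter_smooth_ms * fs / 1000.0)))
    jitter = _moving_average(rng.standard_normal(n + 2 * win), win)[win:win + n]
    sd = jitter.std()
    if sd > 0:
        jitter = jitter / sd * cfg.jitter_sd
    wander = scan + jitter
    margin = 1.0
    dev_max = np.maximum(halfw[side] - margin, 0.1)
    # squash scale ~1.3 sd of the wander: keeps the tanh mostly linear while
    # still guaranteeing the trace cannot cross the midline between switches
    wander_scale = 1.3 * math.sqrt(cfg.scan_amp ** 2 / 2.0 + cfg.jitter_sd ** 2)
    x = base + dev_max * np.tanh(wander / max(wander_scale, 1e-6))
    x = np.clip(x, lo, hi)

    y = 30.0 + _moving_average(rng.standard_normal(n), max(1, int(fs * 0.1)))
    y = np.clip(y * 4.0, 0.0, 60.0)
    return PositionTrace(x=x, fs=fs, y=y)


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------

def default_forward_pattern(n_channels: int, fs: float, seed: int = 0,
                            lag_min_ms: float = -200.0,
                            lag_max_ms: float = 400.0) -> tuple[np.ndarray, np.ndarray]:
    """A smooth rank-one channels x lags mixing kernel and its sample lags.

    Spatial profile: graded positive-to-negative across the montage with a
    little seeded roughness; temporal profile: bipolar bump peaking ~80 ms
    after the velocity it encodes.
    """
    lags = lag_samples(lag_min_ms, lag_max_ms, fs)
    t_ms = lags / fs * 1000.0
    h = np.exp(-0.5 * ((t_ms - 80.0) / 60.0) ** 2) * np.cos(2 * np.pi * (t_ms - 80.0) / 320.0)
    rng = spawn_rng(seed, _STAGE_EEG, 0)
    i = np.arange(n_channels)
    a = np.cos(np.pi * i / max(n_channels - 1, 1)) + 0.3 * np.sin(2 * np.pi * i / max(n_channels, 1))
    a = a + 0.15 * rng.standard_normal(n_channels)
    pattern = np.outer(a, h)
    pattern /= np.max(np.abs(pattern))
    return pattern, lags


def simulate_eeg(velocity: np.ndarray, pattern: np.ndarray, snr: float,
                 seed: int, fs: float, lags: np.ndarray | None = None,
                 labels: list[str] | None = None) -> EEGTrace:
    """Lagged linear mixture of velocity plus channel noise at ratio ``snr``.

    Each channel is the convolution of the velocity with that channel's lag
    kernel plus white Gaussian noise scaled so var(signal)/var(noise) = snr.
    ``snr = 0`` yields pure unit-variance noise.
    """
    if snr < 0:
        raise ValueError("snr must be >= 0")
    velocity = np.asarray(velocity, dtype=float)
    pattern = np.asarray(pattern, dtype=float)
    n_channels = pattern.shape[0]
    if lags is None:
        lags = lag_samples(-200.0, 400.0, fs)
    if np.min(lags) / fs * 1000.0 < -200.0 - 1e-9 or np.max(lags) / fs * 1000.0 > 400.0 + 1e-9:
        raise ValueError("pattern lags must lie within [-200, +400] ms")
    if labels is None:
        labels = channel_labels(n_channels)
    rng = spawn_rng(seed, _STAGE_EEG, 1)
    noise = rng.standard_normal((velocity.size, n_channels))
    if snr == 0:
        return EEGTrace(data=noise, fs=fs, labels=labels)
    signal = apply_lag_kernel(velocity, pattern, lags)
    sig_var = signal.var(axis=0)
    fallback = sig_var[sig_var > 0].mean() if np.any(sig_var > 0) else 1.0
    noise_sd = np.sqrt(np.where(sig_var > 0, sig_var, fallback) / snr)
    return EEGTrace(data=signal + noise * noise_sd, fs=fs, labels=labels)


# ---------------------------------------------------------------------------
# behavior
# ---------------------------------------------------------------------------

def simulate_behavior(drift: float, boundary: float, ndt: float, w: float,
                      seed: int, dt: float = 5e-4) -> tuple[str, float]:
    """One diffusion trial; returns (choice in {"upper","lower"}, rt in s)."""
    choices, rts = simulate_paths(1, drift, boundary, w, ndt, seed=seed, dt=dt)
    return ("upper" if choices[0] == 1 else "lower"), float(rts[0])


def _draw_participant_params(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    truth = cfg.true_ddm.resolve(cfg.conditions)
    sd = cfg.true_ddm.participant_sd
    rows = []
    for p in range(cfg.n_participants):
        for c in cfg.conditions:
            row = {"participant": p, "condition": c}
            for name, group in truth.items():
                val = group[c] + sd.get(name, 0.0) * rng.standard_normal()
                if name == "alpha":
                    val = max(val, 0.3)
                if name == "beta0":
                    val = max(val, 0.1)
                row[name] = val
            rows.append(row)
    return pd.DataFrame(rows)


def _choice_labels(correct: np.ndarray, low_side: np.ndarray) -> np.ndarray:
    high_side = np.where(low_side == "L", "R", "L")
    return np.where(correct == 1, high_side, np.where(high_side == "R", "L", "R"))


def generate_behavior_table(cfg: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Fast behavior-only generation (no traces or EEG).

    Movement covariates are drawn from simple parametric distributions with
    the same coupling into nondecision time as the full generator, and the
    ``r2`` column holds the *latent* per-trial coupling strength, so decision
    parameters can be recovered without running the decoding stage.
    """
    cfg.validate()
    rng = spawn_rng(cfg.seed, _STAGE_MISC)
    pp = _draw_participant_params(cfg, rng)
    pp_idx = pp.set_index(["participant", "condition"])

    rows = []
    for p in range(cfg.n_participants):
        for c in cfg.conditions:
            par = pp_idx.loc[(p, c)]
            for ai, amp in enumerate(cfg.amplitude_levels):
                for k in range(cfg.n_trials_per_cell):
                    trng = spawn_rng(cfg.seed, _STAGE_DDM, p,
                                     cfg.conditions.index(c), ai, k)
                    s = abs(amp - cfg.reference_amplitude)
                    low = "L" if trng.random() < 0.5 else "R"
                    if amp > cfg.reference_amplitude:
                        low = "R" if low == "L" else "L"  # comparison side random too
                    a_beta, b_beta = cfg.coupling_beta
                    rho = float(trng.beta(a_beta, b_beta) * cfg.coupling_scale)
                    drift = par["gamma0"] + par["gamma1"] * rho * s
                    rows.append({
                        "participant": p, "condition": c, "amp": amp, "s": s,
                        "amplitude_low_side": low, "rho": rho, "drift": drift,
                        "alpha": par["alpha"], "beta0": par["beta0"],
                        "beta_sw": par["beta_sw"], "beta_exp": par["beta_exp"],
                        "frac_low": float(trng.beta(5.0, 5.0)),
                        "u_ncr": trng.random(),
                        "explore": float(trng.lognormal(np.log(3.0), 0.35)),
                        "v_m": float(trng.lognormal(np.log(45.0), 0.25)),
                    })
    tab = pd.DataFrame(rows)

    choices, t_dec, _ = simulate_paths_per_trial(
        tab["drift"].to_numpy(), tab["alpha"].to_numpy(),
        np.zeros(len(tab)), cfg.true_ddm.w,
        seed=int(spawn_rng(cfg.seed, _STAGE_DDM).integers(2**31)),
        dt=cfg.ddm_dt)

    # nondecision time from *exogenous* movement covariates: the exploration
    # horizon is drawn independently of the decision time, so the regression
    # covariates n_cr and t_low carry no information about the diffusion
    # outcome itself (keeps parameter recovery unbiased)
    frac = tab["frac_low"].to_numpy()
    beta0 = tab["beta0"].to_numpy()
    bsw = tab["beta_sw"].to_numpy()
    bexp = tab["beta_exp"].to_numpy()
    horizon = tab["explore"].to_numpy()
    from scipy import stats as _st
    n_cr = _st.poisson.ppf(tab["u_ncr"].to_numpy(),
                           np.maximum(cfg.switch_rate * horizon, 1e-9)).astype(int)
    t_low = frac * horizon
    ndt = beta0 + bsw * n_cr + bexp * t_low
    rt = t_dec + ndt

    correct = choices.astype(int)
    out = pd.DataFrame({
        "participant": tab["participant"],
        "condition": tab["condition"],
        "trial": np.arange(len(tab)),
        "s": tab["s"],
        "amp": tab["amp"],
        "amplitude_low_side": tab["amplitude_low_side"],
        "choice": _choice_labels(correct, tab["amplitude_low_side"].to_numpy()),
        "accuracy": correct,
        "rt": rt,
        "v_m": tab["v_m"],
        "n_cr": n_cr,
        "t_low": t_low,
        "r2": tab["rho"],
    })
    truth = GroundTruth(seed=cfg.seed, true_ddm=copy.deepcopy(cfg.true_ddm),
                        participant_params=pp,
                        latent_coupling=tab["rho"].to_numpy(),
                        true_drift=tab["drift"].to_numpy())
    return out, truth


def generate_dataset(cfg: SimConfig) -> tuple[Dataset, GroundTruth]:
    """Full dataset: trajectory, EEG, choice and RT for every trial cell.

    Trial length is solved as a fixed point: the nondecision time depends on
    the movement parameters measured over the trial window, which itself ends
    at decision time + nondecision time.
    """
    cfg.validate()
    rng = spawn_rng(cfg.seed, _STAGE_MISC)
    pp = _draw_participant_params(cfg, rng)
    pp_idx = pp.set_index(["participant", "condition"])
    pattern, lags = default_forward_pattern(cfg.n_channels, cfg.fs, cfg.seed,
                                            cfg.lag_min_ms, cfg.lag_max_ms)
    labels = channel_labels(cfg.n_channels)
    snr_cond = cfg.snr_by_condition
    rho_mean = cfg.coupling_scale * cfg.coupling_beta[0] / sum(cfg.coupling_beta)

    trials: list[TrialRecording] = []
    couplings: list[float] = []
    drifts: list[float] = []
    horizon = 14.0  # pre-simulated trajectory length, > QC rt cap
    for p in range(cfg.n_participants):
        for ci, c in enumerate(cfg.conditions):
            par = pp_idx.loc[(p, c)]
            tcount = 0
            for ai, amp in enumerate(cfg.amplitude_levels):
                for k in range(cfg.n_trials_per_cell):
                    trng = spawn_rng(cfg.seed, _STAGE_DDM, p, ci, ai, k)
                    s = abs(amp - cfg.reference_amplitude)
                    low = "L" if trng.random() < 0.5 else "R"
                    a_beta, b_beta = cfg.coupling_beta
                    rho = float(trng.beta(a_beta, b_beta) * cfg.coupling_scale)
                    drift = float(par["gamma0"] + par["gamma1"] * rho * s)
                    em_seed = int(trng.integers(2**31))
                    ch, t_dec_arr, _ = simulate_paths_per_trial(
                        np.array([drift]), np.array([par["alpha"]]),
                        np.array([0.0]), cfg.true_ddm.w, seed=em_seed,
                        dt=cfg.ddm_dt)
                    t_dec = float(t_dec_arr[0])
                    correct = int(ch[0])

                    traj_seed = int(trng.integers(2**31))
                    full = simulate_trajectory(cfg, horizon, traj_seed)
                    # fixed point on the trial window length
                    L = t_dec + par["beta0"] + 0.5
                    for _ in range(8):
                        nwin = int(np.clip(round(L * cfg.fs), 2, full.x.size))
                        sub = PositionTrace(x=full.x[:nwin], fs=cfg.fs)
                        mp = movement_parameters(sub, cfg.midline_x, low)
                        ndt = (par["beta0"] + par["beta_sw"] * mp.n_cr
                               + par["beta_exp"] * mp.t_low)
                        L_new = t_dec + ndt
                        if abs(L_new - L) < 1.0 / cfg.fs:
                            L = L_new
                            break
                        L = L_new
                    nwin = int(np.clip(round(L * cfg.fs), 2, full.x.size))
                    pos = PositionTrace(x=full.x[:nwin], fs=cfg.fs,
                                        y=None if full.y is None else full.y[:nwin])
                    mp = movement_parameters(pos, cfg.midline_x, low)
                    ndt = (par["beta0"] + par["beta_sw"] * mp.n_cr
                           + par["beta_exp"] * mp.t_low)
                    rt = t_dec + ndt

                    vel = np.gradient(pos.x, 1.0 / cfg.fs)
                    snr_t = snr_cond[c] * rho / rho_mean
                    eeg = simulate_eeg(vel, pattern, snr_t,
                                       seed=int(trng.integers(2**31)),
                                       fs=cfg.fs, lags=lags, labels=labels)
                    choice = _choice_labels(np.array([correct]),
                                            np.array([low]))[0]
                    trials.append(TrialRecording(
                        participant=p, condition=c, trial=tcount,
                        position=pos, eeg=eeg, s=s, amplitude_low_side=low,
                        choice=str(choice), accuracy=correct, rt=float(rt),
                        meta={"latent_coupling": rho, "amp": amp,
                              "seed": cfg.seed}))
                    couplings.append(rho)
                    drifts.append(drift)
                    tcount += 1

    ds = Dataset(trials=trials, fs=cfg.fs, channel_labels=labels,
                 midline_x=cfg.midline_x, meta={"seed": cfg.seed})
    truth = GroundTruth(seed=cfg.seed, true_ddm=copy.deepcopy(cfg.true_ddm),
                        lags=lags, forward_pattern=pattern,
                        participant_params=pp,
                        latent_coupling=np.array(couplings),
                        true_drift=np.array(drifts))
    return ds, truth
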