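"""Lagged ridge decoding of finger velocity from multichannel EEG.

A single decoder per participant x condition is trained on concatenated
trials; single-trial reconstruction accuracy (squared Pearson correlation)
is computed by 5-fold cross-fitting so no trial is scored by a decoder that
saw it.  Decoding weights are inverted to interpretable forward (encoding)
patterns via the covariance transform
``f = (X^T X) g / (s_hat^T s_hat)`` on centered data.

Columns of the lagged design are ordered channel-major, lag-minor:
column ``i * n_lags + j`` holds channel ``i`` shifted by lag ``lags[j]``
(``X[t, .] = m[t + lag_j, i]``), zero-padded at trial edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import lag_samples, shift
from .dataset import EEGTrace

__all__ = [
    "LagSpec",
    "DecoderModel",
    "ForwardModel",
    "ReconstructionScore",
    "DEFAULT_LAMBDA",
    "DEFAULT_LAMBDA_GRID",
    "build_lagged_design",
    "fit_ridge",
    "train_decoder",
    "predict_velocity",
    "select_lambda_cv",
    "score_single_trials",
    "score_train_test",
    "to_forward_model",
    "apply_encoding_model",
]

# the pipeline default fixes lambda = 2**2 (cross-validated curves are flat
# over 2**0..2**4, so one value is used everywhere for consistency)
DEFAULT_LAMBDA = 4.0
DEFAULT_LAMBDA_GRID = tuple(float(2 ** k) for k in range(0, 21))


@dataclass(frozen=True)
class LagSpec:
    fs: float
    lag_min_ms: float = -200.0
    lag_max_ms: float = 400.0

    def __post_init__(self) -> None:
        if self.lag_min_ms >= self.lag_max_ms:
            raise ValueError("lag_min_ms must be < lag_max_ms")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def lags(self) -> np.ndarray:
        return lag_samples(self.lag_min_ms, self.lag_max_ms, self.fs)

    @property
    def n_lags(self) -> int:
        return self.lags.size


@dataclass
class DecoderModel:
    """Backward model: weights g over channels x lags plus standardization."""

    g: np.ndarray                # (n_channels, n_lags), native units
    intercept: float
    lam: float
    lag_spec: LagSpec
    channel_labels: list[str]
    training_trials: list = field(default_factory=list)

    @property
    def weights_flat(self) -> np.ndarray:
        return self.g.reshape(-1)


@dataclass
class ForwardModel:
    """Encoding pattern f over channels x lags (covariance-transformed)."""

    f: np.ndarray                # (n_channels, n_lags)
    lag_spec: LagSpec
    channel_labels: list[str]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.f)):
            raise ValueError("forward pattern must be finite")


@dataclass
class ReconstructionScore:
    trial_ids: list
    r2: np.ndarray
    reconstructed: list          # s_hat(t) per trial
    measured: list               # s(t) per trial
    flagged: list = field(default_factory=list)


def build_lagged_design(eeg: EEGTrace | np.ndarray, lag_spec: LagSpec) -> np.ndarray:
    """Time x (channels * lags) design of lagged EEG copies, zero-padded."""
    if isinstance(eeg, EEGTrace):
        if abs(eeg.fs - lag_spec.fs) > 1e-9:
            raise ValueError("EEG sampling rate must match the lag spec")
        data = eeg.data
    else:
        data = np.asarray(eeg, dtype=float)
        if data.ndim == 1:
            data = data[:, None]
    lags = lag_spec.lags
    if data.shape[0] <= lags.size:
        raise ValueError("trial shorter than the lag span")
    cols = []
    for i in range(data.shape[1]):
        for k in lags:
            cols.append(shift(data[:, i], -int(k)))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# ridge core (standardized normal equations assembled from raw cross-products)
# ---------------------------------------------------------------------------

@dataclass
class _CrossProducts:
    sxx: np.ndarray
    sxy: np.ndarray
    sx: np.ndarray
    sy: float
    syy: float
    n: int

    def __add__(self, other: "_CrossProducts") -> "_CrossProducts":
        return _CrossProducts(self.sxx + other.sxx, self.sxy + other.sxy,
                              self.sx + other.sx, self.sy + other.sy,
                              self.syy + other.syy, self.n + other.n)

    def __sub__(self, other: "_CrossProducts") -> "_CrossProducts":
        return _CrossProducts(self.sxx - other.sxx, self.sxy - other.sxy,
                              self.sx - other.sx, self.sy - other.sy,
                              self.syy - other.syy, self.n - other.n)


def _cross_products(X: np.ndarray, y: np.ndarray) -> _CrossProducts:
    return _CrossProducts(X.T @ X, X.T @ y, X.sum(axis=0), float(y.sum()),
                          float(y @ y), X.shape[0])


def _solve_standardized(cp: _CrossProducts, lam: float):
    """Ridge solution in z-scored space, back-transformed to native units."""
    n = cp.n
    mu = cp.sx / n
    var = np.maximum(np.diag(cp.sxx) / n - mu ** 2, 0.0)
    y_mu = cp.sy / n
    y_var = max(cp.syy / n - y_mu ** 2, 0.0)
    if y_var == 0:
        raise ValueError("target has zero variance")
    dead = var <= 1e-12 * max(var.max(), 1.0)
    sd = np.sqrt(np.where(dead, 1.0, var))
    y_sd = np.sqrt(y_var)

    G = (cp.sxx - n * np.outer(mu, mu)) / np.outer(sd, sd)
    b = (cp.sxy - n * mu * y_mu) / (sd * y_sd)
    if dead.any():
        G[dead, :] = 0.0
        G[:, dead] = 0.0
        G[dead, dead] = 1.0
        b[dead] = 0.0
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if lam == 0:
        # guard against singular systems: advise regularization
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e10:
            raise np.linalg.LinAlgError(
                "design is singular/collinear at lambda=0; use lambda > 0")
        w_std = np.linalg.solve(G, b)
    else:
        w_std = np.linalg.solve(G + lam * np.eye(G.shape[0]), b)
    w = w_std * y_sd / sd
    w[dead] = 0.0
    intercept = y_mu - float(mu @ w)
    return w, intercept


def fit_ridge(design: np.ndarray, target: np.ndarray, lam: float):
    """Ridge regression with internal z-scoring; returns (weights, intercept).

    Weights solve ``(Xz' Xz + lam I) w = Xz' yz`` in the standardized space
    and are back-transformed for prediction in native units.
    """
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float)
    if design.shape[0] != target.shape[0]:
        raise ValueError("design rows must match target length")
    return _solve_standardized(_cross_products(design, target), lam)


def _trial_arrays(trials, lag_spec: LagSpec):
    """(design, velocity) per trial; trials are TrialRecording-like objects."""
    out = []
    for t in trials:
        out.append((build_lagged_design(t.eeg, lag_spec),
                    np.asarray(t.velocity, dtype=float)))
    return out


def train_decoder(trials, lag_spec: LagSpec, lam: float = DEFAULT_LAMBDA) -> DecoderModel:
    """Fit one decoder on the concatenation of the given trials."""
    if not trials:
        raise ValueError("no trials to train on")
    cp = None
    for X, y in _trial_arrays(trials, lag_spec):
        c = _cross_products(X, y)
        cp = c if cp is None else cp + c
    w, b = _solve_standardized(cp, lam)
    labels = list(trials[0].eeg.labels)
    g = w.reshape(len(labels), lag_spec.n_lags)
    return DecoderModel(g=g, intercept=b, lam=lam, lag_spec=lag_spec,
                        channel_labels=labels,
                        training_trials=[getattr(t, "trial", i) for i, t in enumerate(trials)])


def predict_velocity(model: DecoderModel, eeg: EEGTrace | np.ndarray) -> np.ndarray:
    X = build_lagged_design(eeg, model.lag_spec)
    return X @ model.weights_flat + model.intercept


def _r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return np.nan
    c = float(np.corrcoef(a, b)[0, 1])
    return c * c


def _fold_assignment(n: int, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0xF01D)))
    perm = rng.permutation(n)
    folds = np.empty(n, dtype=int)
    folds[perm] = np.arange(n) % n_folds
    return folds


def select_lambda_cv(trials, lag_spec: LagSpec,
                     grid=DEFAULT_LAMBDA_GRID, n_folds: int = 5,
                     seed: int = 0):
    """Trial-wise k-fold CV over a lambda grid on the training trials.

    Returns ``(lam_star, curve)`` where ``curve`` maps lambda to the mean
    held-out r^2.  A flatness warning is raised when the curve is
    uninformative (range below 0.01), mirroring null data behavior.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("lambda grid is empty")
    if len(trials) < n_folds:
        raise ValueError(f"need >= {n_folds} training trials")
    arrays = _trial_arrays(trials, lag_spec)
    cps = [_cross_products(X, y) for X, y in arrays]
    total = cps[0]
    for c in cps[1:]:
        total = total + c
    folds = _fold_assignment(len(trials), n_folds, seed)

    curve = {}
    for lam in grid:
        scores = []
        for f in range(n_folds):
            fold_cp = None
            for i in np.where(folds == f)[0]:
                fold_cp = cps[i] if fold_cp is None else fold_cp + cps[i]
            w, b = _solve_standardized(total - fold_cp, lam)
            for i in np.where(folds == f)[0]:
                X, y = arrays[i]
                r2 = _r2(X @ w + b, y)
                if not np.isnan(r2):
                    scores.append(r2)
        curve[lam] = float(np.mean(scores)) if scores else np.nan
    lam_star = max(curve, key=lambda k: (curve[k], -k))
    vals = np.array(list(curve.values()))
    if np.nanmax(vals) - np.nanmin(vals) < 0.01:
        warnings.warn("cv curve is flat; lambda selection is uninformative",
                      stacklevel=2)
    return lam_star, curve


def score_single_trials(trials, lag_spec: LagSpec, lam: float = DEFAULT_LAMBDA,
                        n_folds: int = 5, seed: int = 0) -> ReconstructionScore:
    """Per-trial r^2 by k-fold cross-fitting across trials.

    Each trial is scored by a decoder trained on the trials outside its
    fold.  Trials whose velocity or reconstruction is degenerate are flagged
    and receive r^2 = nan.
    """
    if not trials:
        raise ValueError("no trials")
    arrays = _trial_arrays(trials, lag_spec)
    cps = [_cross_products(X, y) for X, y in arrays]
    total = cps[0]
    for c in cps[1:]:
        total = total + c
    n_folds = min(n_folds, len(trials))
    folds = _fold_assignment(len(trials), n_folds, seed)

    r2 = np.full(len(trials), np.nan)
    recon: list = [None] * len(trials)
    measured: list = [None] * len(trials)
    flagged = []
    for f in range(n_folds):
        idx = np.where(folds == f)[0]
        fold_cp = None
        for i in idx:
            fold_cp = cps[i] if fold_cp is None else fold_cp + cps[i]
        train_cp = total - fold_cp
        if train_cp.n == 0:
            raise ValueError("cross-fitting requires more than one fold of data")
        w, b = _solve_standardized(train_cp, lam)
        for i in idx:
            X, y = arrays[i]
            yhat = X @ w + b
            recon[i] = yhat
            measured[i] = y
            val = _r2(yhat, y)
            if np.isnan(val):
                flagged.append(i)
            else:
                r2[i] = val
    ids = [getattr(t, "trial", i) for i, t in enumerate(trials)]
    return ReconstructionScore(trial_ids=ids, r2=r2, reconstructed=recon,
                               measured=measured, flagged=flagged)


def score_train_test(trials, lag_spec: LagSpec, lam: float = DEFAULT_LAMBDA,
                     train_frac: float = 0.8, seed: int = 0):
    """Outer 80/20 split: train on the training partition, score the rest.

    Returns ``(model, test_indices, r2_per_test_trial)``.
    """
    n = len(trials)
    if n < 2:
        raise ValueError("need >= 2 trials")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 0x8020)))
    perm = rng.permutation(n)
    n_train = max(1, int(round(train_frac * n)))
    train_idx, test_idx = perm[:n_train], perm[n_train:]
    model = train_decoder([trials[i] for i in train_idx], lag_spec, lam)
    scores = np.array([
        _r2(predict_velocity(model, trials[i].eeg), np.asarray(trials[i].velocity))
        for i in test_idx
    ])
    return model, test_idx, scores


def to_forward_model(decoder: DecoderModel, trials) -> ForwardModel:
    """Invert a backward model into an encoding pattern on the given data.

    Computes ``f = (Xc^T Xc) g / (s_hat_c^T s_hat_c)`` with centered
    concatenated lagged data Xc and centered reconstruction s_hat.
    """
    Xs = []
    for t in trials:
        Xs.append(build_lagged_design(t.eeg, decoder.lag_spec))
    X = np.vstack(Xs)
    Xc = X - X.mean(axis=0)
    w = decoder.weights_flat
    shat = Xc @ w
    denom = float(shat @ shat)
    if denom <= 0:
        raise ValueError("reconstruction has zero variance; cannot invert")
    f = (Xc.T @ shat) / denom  # == (Xc'Xc) g / (shat' shat)
    return ForwardModel(f=f.reshape(decoder.g.shape), lag_spec=decoder.lag_spec,
                        channel_labels=list(decoder.channel_labels))


def apply_encoding_model(forward: ForwardModel, velocity: np.ndarray) -> np.ndarray:
    """Predict per-channel EEG activity from velocity with a forward pattern.

    Returns (n_samples, n_channels); channel i is the velocity convolved
    with that channel's lag kernel ``f[i, :]``.
    """
    from ._utils import apply_lag_kernel
    return apply_lag_kernel(np.asarray(velocity, dtype=float), forward.f,
                            forward.lag_spec.lags)
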