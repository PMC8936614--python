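"""Redundant / unique / synergistic interactions between encoding models.

For each EEG channel the predictions of the two unisensory encoding models
(V, H) are used to explain the prediction of the multisensory (VH) model.
Mutual information is estimated for Gaussian-copula-normalized variables in
bits; redundancy uses the common-change-in-surprisal criterion: the
expectation of the pointwise co-information restricted to samples where the
pointwise information changes of V, H, the joint, and the co-information all
share one sign.  Unique and synergistic atoms follow from the lattice
identities, which therefore hold exactly by construction:

    I_red + I_unique_V = I(T;V)
    I_red + I_unique_H = I(T;H)
    I_red + I_unique_V + I_unique_H + I_syn = I(T;[V,H])
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import spawn_rng
from .trf_decoding import (LagSpec, ForwardModel, apply_encoding_model,
                           to_forward_model, train_decoder, DEFAULT_LAMBDA)

__all__ = [
    "PredictionTriplet",
    "PIDAtoms",
    "PIDResult",
    "copula_normalize",
    "gaussian_mi",
    "co_information",
    "pid_ccs",
    "pid_mmi",
    "channelwise_pid",
    "permutation_test",
]

ATOM_NAMES = ("redundancy", "unique_v", "unique_h", "synergy")


@dataclass
class PredictionTriplet:
    """Per-channel model predictions over the VH trials, kept per trial."""

    channel: str
    segments: list  # list of (target_seg, v_seg, h_seg) arrays, one per trial

    def __post_init__(self) -> None:
        for t, v, h in self.segments:
            if not (len(t) == len(v) == len(h)):
                raise ValueError("triplet segments must have equal lengths")
            if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))
                    and np.all(np.isfinite(h))):
                raise ValueError("triplet contains non-finite values")
        if self.n_samples < 100:
            raise ValueError("need >= 100 samples per channel")

    @property
    def n_samples(self) -> int:
        return sum(len(t) for t, _, _ in self.segments)

    @property
    def target(self) -> np.ndarray:
        return np.concatenate([t for t, _, _ in self.segments])

    @property
    def pred_v(self) -> np.ndarray:
        return np.concatenate([v for _, v, _ in self.segments])

    @property
    def pred_h(self) -> np.ndarray:
        return np.concatenate([h for _, _, h in self.segments])


@dataclass
class PIDAtoms:
    redundancy: float
    unique_v: float
    unique_h: float
    synergy: float
    mi_v: float       # I(T;V)
    mi_h: float       # I(T;H)
    mi_joint: float   # I(T;[V,H])
    co_info: float    # I(T;V) + I(T;H) - I(T;[V,H])
    negative_unique_flag: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("redundancy", "unique_v", "unique_h", "synergy",
                 "mi_v", "mi_h", "mi_joint", "co_info")}


@dataclass
class PIDResult:
    table: pd.DataFrame            # channel x atom values, p, significance
    null_distributions: dict = field(default_factory=dict)


def copula_normalize(samples: np.ndarray) -> np.ndarray:
    """Rank-transform then map to standard-normal quantiles.

    Output has an (empirically) standard-normal marginal and preserves rank
    order, making downstream estimates invariant to monotone transforms.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("copula_normalize expects a 1-D series")
    if x.size < 10:
        raise ValueError("need >= 10 samples")
    _, counts = np.unique(x, return_counts=True)
    if counts.max() > 0.5 * x.size:
        warnings.warn("more than 50% tied values; copula transform is unreliable",
                      stacklevel=2)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (x.size + 1.0))


def _as_2d(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[:, None] if a.ndim == 1 else a


def _logdet(c: np.ndarray) -> float:
    sign, val = np.linalg.slogdet(np.atleast_2d(c))
    if sign <= 0:
        raise np.linalg.LinAlgError("singular covariance")
    return float(val)


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Gaussian mutual information in bits from sample covariances.

    ``0.5 * log2(det(Sx) * det(Sy) / det(Sxy))``; raises on singular joint
    covariance (e.g. ``y`` an exact copy of ``x``).
    """
    X, Y = _as_2d(x), _as_2d(y)
    if X.shape[0] != Y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    Z = np.hstack([X, Y])
    if not np.all(np.isfinite(Z)):
        raise ValueError("inputs must be finite")
    S = np.cov(Z, rowvar=False)
    dx = X.shape[1]
    try:
        ld_joint = _logdet(S)
        ld_x = _logdet(S[:dx, :dx])
        ld_y = _logdet(S[dx:, dx:])
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"singular covariance in gaussian_mi: {e}")
    return 0.5 * (ld_x + ld_y - ld_joint) / np.log(2.0)


def co_information(triplet: PredictionTriplet | tuple) -> float:
    """I(T;V) + I(T;H) - I(T;[V,H]); positive = net redundancy."""
    t, v, h = _unpack(triplet)
    return (gaussian_mi(t, v) + gaussian_mi(t, h)
            - gaussian_mi(t, np.column_stack([v, h])))


def _unpack(triplet):
    if isinstance(triplet, PredictionTriplet):
        return triplet.target, triplet.pred_v, triplet.pred_h
    t, v, h = triplet
    return (np.asarray(t, dtype=float), np.asarray(v, dtype=float),
            np.asarray(h, dtype=float))


def _gauss_logpdf(z: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Row-wise log2 density of centered data under N(mean(z), cov)."""
    z = _as_2d(z)
    mu = z.mean(axis=0)
    d = z - mu
    cinv = np.linalg.inv(cov)
    ld = _logdet(cov)
    q = np.einsum("ij,jk,ik->i", d, cinv, d)
    ln = -0.5 * (q + ld + z.shape[1] * np.log(2.0 * np.pi))
    return ln / np.log(2.0)


def pid_ccs(triplet: PredictionTriplet | tuple, normalized: bool = False,
            tol: float = 1e-6) -> PIDAtoms:
    """Four-atom decomposition with common-change-in-surprisal redundancy.

    Inputs are copula-normalized unless ``normalized=True``.  All pointwise
    surprisals are evaluated under the fitted joint Gaussian.
    """
    t, v, h = _unpack(triplet)
    if not normalized:
        t, v, h = (copula_normalize(a) for a in (t, v, h))
    Z = np.column_stack([t, v, h])
    S = np.cov(Z, rowvar=False)

    mi_v = gaussian_mi(t, v)
    mi_h = gaussian_mi(t, h)
    mi_joint = gaussian_mi(t, np.column_stack([v, h]))

    # pointwise information terms (log2 ratios under the fitted Gaussian)
    lp_t = _gauss_logpdf(t, S[:1, :1])
    lp_v = _gauss_logpdf(v, S[1:2, 1:2])
    lp_h = _gauss_logpdf(h, S[2:3, 2:3])
    lp_tv = _gauss_logpdf(Z[:, [0, 1]], S[np.ix_([0, 1], [0, 1])])
    lp_th = _gauss_logpdf(Z[:, [0, 2]], S[np.ix_([0, 2], [0, 2])])
    lp_vh = _gauss_logpdf(Z[:, [1, 2]], S[np.ix_([1, 2], [1, 2])])
    lp_tvh = _gauss_logpdf(Z, S)

    i_v = lp_tv - lp_t - lp_v
    i_h = lp_th - lp_t - lp_h
    i_joint = lp_tvh - lp_vh - lp_t
    c = i_v + i_h - i_joint

    common = ((np.sign(i_v) == np.sign(i_h))
              & (np.sign(i_v) == np.sign(i_joint))
              & (np.sign(i_v) == np.sign(c))
              & (np.sign(i_v) != 0))
    red = float(np.mean(np.where(common, c, 0.0)))

    unique_v = mi_v - red
    unique_h = mi_h - red
    synergy = mi_joint - red - unique_v - unique_h
    flag = (unique_v < -tol) or (unique_h < -tol)
    return PIDAtoms(redundancy=red, unique_v=unique_v, unique_h=unique_h,
                    synergy=synergy, mi_v=mi_v, mi_h=mi_h, mi_joint=mi_joint,
                    co_info=mi_v + mi_h - mi_joint, negative_unique_flag=flag)


def pid_mmi(triplet: PredictionTriplet | tuple, normalized: bool = False) -> PIDAtoms:
    """Fallback decomposition: redundancy = min(I(T;V), I(T;H))."""
    t, v, h = _unpack(triplet)
    if not normalized:
        t, v, h = (copula_normalize(a) for a in (t, v, h))
    mi_v = gaussian_mi(t, v)
    mi_h = gaussian_mi(t, h)
    mi_joint = gaussian_mi(t, np.column_stack([v, h]))
    red = min(mi_v, mi_h)
    return PIDAtoms(redundancy=red, unique_v=mi_v - red, unique_h=mi_h - red,
                    synergy=mi_joint - mi_v - mi_h + red, mi_v=mi_v, mi_h=mi_h,
                    mi_joint=mi_joint, co_info=mi_v + mi_h - mi_joint)


_ESTIMATORS = {"ccs": pid_ccs, "mmi": pid_mmi}


@dataclass
class EncodingPermutationContext:
    """Cached state to rebuild the target predictions under a permuted
    velocity <-> EEG pairing of the training trials (the "refit" null).

    All trials are truncated to a common length so per-trial design
    cross-products can be cached; each permutation then costs one ridge
    solve per fold plus the per-channel decomposition.
    """

    labels: list
    lags: np.ndarray
    lam: float
    folds: np.ndarray
    designs: list          # per trial: (L, d) lagged EEG design
    velocities: list       # per trial: (L,)
    pred_v: list           # per trial: (L, n_ch) fixed unisensory predictions
    pred_h: list

    def _fold_cache(self, f: int):
        if not hasattr(self, "_cache"):
            self._cache = {}
        if f not in self._cache:
            train = np.where(self.folds != f)[0]
            X = np.vstack([self.designs[i] for i in train])
            Xc = X - X.mean(axis=0)
            self._cache[f] = (train, X, Xc, Xc.T @ Xc)
        return self._cache[f]

    def _fit_fold(self, f: int, order: np.ndarray) -> np.ndarray:
        from .trf_decoding import _CrossProducts, _solve_standardized
        train, X, Xc, gram_c = self._fold_cache(f)
        y = np.concatenate([self.velocities[order[i]] for i in train])
        cp = _CrossProducts(sxx=gram_c + 0.0, sxy=X.T @ y, sx=X.sum(axis=0),
                            sy=float(y.sum()), syy=float(y @ y), n=X.shape[0])
        # gram_c is centered; _solve_standardized expects raw sums of squares
        mu = cp.sx / cp.n
        cp.sxx = gram_c + cp.n * np.outer(mu, mu)
        w, _ = _solve_standardized(cp, self.lam)
        cov_w = gram_c @ w
        denom = float(w @ cov_w)
        if denom <= 0:
            raise ValueError("degenerate surrogate reconstruction")
        return (cov_w / denom).reshape(len(self.labels), -1)

    def atoms_for_order(self, order: np.ndarray, estimate) -> dict:
        """Per-channel atoms with the target model refit under ``order``."""
        from ._utils import apply_lag_kernel
        n_trials = len(self.designs)
        target = {ch: [None] * n_trials for ch in self.labels}
        for f in np.unique(self.folds):
            f_pat = self._fit_fold(int(f), order)
            for i in np.where(self.folds == f)[0]:
                pred = apply_lag_kernel(self.velocities[i], f_pat, self.lags)
                for ci, ch in enumerate(self.labels):
                    target[ch][i] = pred[:, ci]
        out = {}
        for ci, ch in enumerate(self.labels):
            t = np.concatenate(target[ch])
            v = np.concatenate([p[:, ci] for p in self.pred_v])
            h = np.concatenate([p[:, ci] for p in self.pred_h])
            out[ch] = estimate((t, v, h))
        return out


def channelwise_pid(vh_trials, v_model: ForwardModel, h_model: ForwardModel,
                    lag_spec: LagSpec, lam: float = DEFAULT_LAMBDA,
                    n_folds: int = 5, seed: int = 0,
                    estimator: str = "ccs", return_context: bool = False):
    """Per-channel triplets and PID atoms over the VH-condition trials.

    The VH encoding model is trained within a 5-fold split of the VH trials
    (decoder on the training folds, inverted to a forward model) and applied
    to held-out trials; the unisensory forward models — trained in their own
    conditions — predict the same held-out trials.  Predictions run in the
    encoding direction (velocity -> channel), one triplet per channel.
    """
    if v_model is None or h_model is None:
        raise ValueError("missing condition models (need both V and H)")
    if estimator not in _ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if len(vh_trials) < n_folds:
        raise ValueError(f"need >= {n_folds} VH trials")
    labels = list(vh_trials[0].eeg.labels)
    rng = spawn_rng(seed, 0x91D)
    perm = rng.permutation(len(vh_trials))
    folds = np.empty(len(vh_trials), dtype=int)
    folds[perm] = np.arange(len(vh_trials)) % n_folds

    segments: dict[str, list] = {ch: [None] * len(vh_trials) for ch in labels}
    for f in range(n_folds):
        train = [vh_trials[i] for i in np.where(folds != f)[0]]
        decoder = train_decoder(train, lag_spec, lam)
        vh_model = to_forward_model(decoder, train)
        for i in np.where(folds == f)[0]:
            vel = np.asarray(vh_trials[i].velocity, dtype=float)
            pred_vh = apply_encoding_model(vh_model, vel)
            pred_v = apply_encoding_model(v_model, vel)
            pred_h = apply_encoding_model(h_model, vel)
            for ci, ch in enumerate(labels):
                segments[ch][i] = (pred_vh[:, ci], pred_v[:, ci], pred_h[:, ci])

    triplets = [PredictionTriplet(channel=ch, segments=segments[ch])
                for ch in labels]
    estimate = _ESTIMATORS[estimator]
    rows = []
    for tr in triplets:
        atoms = estimate(tr)
        rows.append({"channel": tr.channel, **atoms.as_dict(),
                     "negative_unique_flag": getattr(atoms, "negative_unique_flag", False)})
    table = pd.DataFrame(rows)
    if not return_context:
        return triplets, table

    # cache equal-length per-trial state for the refit permutation null
    from .trf_decoding import build_lagged_design
    L = min(t.eeg.n_samples for t in vh_trials)
    designs, velocities, pv, ph = [], [], [], []
    for i, t in enumerate(vh_trials):
        vel = np.asarray(t.velocity, dtype=float)[:L]
        eeg = t.eeg.data[:L]
        designs.append(build_lagged_design(eeg, lag_spec))
        velocities.append(vel)
        pv.append(apply_encoding_model(v_model, vel))
        ph.append(apply_encoding_model(h_model, vel))
    context = EncodingPermutationContext(
        labels=labels, lags=lag_spec.lags, lam=lam, folds=folds,
        designs=designs, velocities=velocities, pred_v=pv, pred_h=ph)
    return triplets, table, context


def _permuted_atoms(triplet: PredictionTriplet, order: np.ndarray,
                    estimate) -> PIDAtoms:
    """Atoms after reassigning target trials (predictors fixed).

    Trial lengths may differ; each permuted pairing is truncated to the
    shorter of the two segments so within-trial autocorrelation is kept.
    """
    segs = []
    for i, j in enumerate(order):
        t_seg = triplet.segments[j][0]
        _, v_seg, h_seg = triplet.segments[i]
        n = min(len(t_seg), len(v_seg))
        segs.append((t_seg[:n], v_seg[:n], h_seg[:n]))
    t = np.concatenate([s[0] for s in segs])
    v = np.concatenate([s[1] for s in segs])
    h = np.concatenate([s[2] for s in segs])
    return estimate((t, v, h))


def permutation_test(triplets, observed: pd.DataFrame | None = None,
                     n_perm: int = 1000, alpha_pct: float = 99.0,
                     q: float = 0.01, seed: int = 0,
                     estimator: str = "ccs",
                     context: EncodingPermutationContext | None = None) -> PIDResult:
    """Permutation null for every atom, with BH-FDR across channels.

    Two nulls are available.  The literal null ("shuffle", used when no
    ``context`` is given) permutes the target signal's trial labels with the
    predictors fixed.  Because all per-channel predictions are deterministic
    filters of the same velocity, that null misses the chance alignment of
    independently fitted kernels and is anticonservative at small lag
    counts; passing the ``context`` from ``channelwise_pid`` switches to a
    stricter, calibrated null that refits the target encoding model after
    shuffling the velocity <-> EEG pairing of its training trials.

    An atom is significant when the observed value exceeds the
    ``alpha_pct`` percentile of its null *and* survives Benjamini-Hochberg
    correction of the plus-one permutation p-values across channels at rate
    ``q``.
    """
    if n_perm < 100:
        raise ValueError("need >= 100 permutations")
    estimate = _ESTIMATORS[estimator]
    n_trials = len(triplets[0].segments)
    if n_trials < 10:
        raise ValueError("need >= 10 trials to permute")

    nulls: dict[str, np.ndarray] = {}
    obs_vals: dict[str, np.ndarray] = {}
    if context is not None:
        rng = spawn_rng(seed, 0x9E2)
        identity = context.atoms_for_order(np.arange(n_trials), estimate)
        for tr in triplets:
            nulls[tr.channel] = np.empty((n_perm, len(ATOM_NAMES)))
            obs_vals[tr.channel] = np.array(
                [getattr(identity[tr.channel], a) for a in ATOM_NAMES])
        for b in range(n_perm):
            order = rng.permutation(n_trials)
            atoms = context.atoms_for_order(order, estimate)
            for ch, at in atoms.items():
                nulls[ch][b] = [getattr(at, a) for a in ATOM_NAMES]
    else:
        if observed is None:
            observed = pd.DataFrame([{"channel": tr.channel,
                                      **estimate(tr).as_dict()}
                                     for tr in triplets])
        obs = observed.set_index("channel")
        for tr in triplets:
            rng = spawn_rng(seed, 0x9E2)
            null = np.empty((n_perm, len(ATOM_NAMES)))
            for b in range(n_perm):
                order = rng.permutation(n_trials)
                atoms = _permuted_atoms(tr, order, estimate)
                null[b] = [getattr(atoms, a) for a in ATOM_NAMES]
            nulls[tr.channel] = null
            obs_vals[tr.channel] = np.array(
                [float(obs.loc[tr.channel, a]) for a in ATOM_NAMES])

    rows = []
    for tr in triplets:
        null = nulls[tr.channel]
        row = {"channel": tr.channel}
        for ai, a in enumerate(ATOM_NAMES):
            o = float(obs_vals[tr.channel][ai])
            row[a] = o
            row[f"p_{a}"] = float((1 + np.count_nonzero(null[:, ai] >= o))
                                  / (1 + n_perm))
            row[f"above_pct_{a}"] = bool(o > np.percentile(null[:, ai], alpha_pct))
        rows.append(row)
    table = pd.DataFrame(rows)
    for a in ATOM_NAMES:
        rej = multipletests(table[f"p_{a}"].to_numpy(), alpha=q,
                            method="fdr_bh")[0]
        table[f"significant_{a}"] = rej & table[f"above_pct_{a}"].to_numpy()
    return PIDResult(table=table, null_distributions=nulls)
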