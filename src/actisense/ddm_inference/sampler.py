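"""Adaptive Metropolis-within-Gibbs sampler for the hierarchical DDM.

Participant-level coefficient vectors (per condition) get random-walk
Metropolis updates against the Wiener first-passage likelihood of their
trials plus their Gaussian group prior; group means are Gibbs-sampled from
truncated normals (uniform box hyperpriors); group standard deviations get
log-scale random-walk updates.  Proposal scales adapt toward ~30%
acceptance during burn-in only, so retained draws come from a fixed kernel.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaincc, gammainccinv, ndtr, ndtri

from numba import njit

from .model import Block, RegressionSpec, build_blocks, block_loglik
from .model import _block_loglik as _block_loglik_nb

__all__ = [
    "PosteriorSamples",
    "sample_posterior",
    "gelman_rubin",
    "posterior_prob",
    "dic",
    "summary",
]

_SD_BOX = (1e-2, 2.0)


def _coef_boxes(spec: RegressionSpec, ndt_hi: float) -> np.ndarray:
    """Uniform prior support (lo, hi) for each coefficient, in spec order.

    Covariates are mean-centered, so the ndt intercept means 'nondecision
    time at average covariates'; its support runs up to a high quantile of
    the observed rts (the likelihood itself rejects rt <= ndt per trial).
    """
    boxes = []
    for cov in spec.drift:
        boxes.append((-20.0, 20.0))
    for cov in spec.ndt:
        if cov == "1":
            boxes.append((0.05, max(ndt_hi, 0.06)))
        else:
            boxes.append((-5.0, 5.0))
    for cov in spec.boundary:
        if cov == "1":
            boxes.append((0.1, 10.0))
        else:
            boxes.append((-5.0, 5.0))
    return np.array(boxes)


@dataclass
class PosteriorSamples:
    """Retained MCMC draws: chains x draws, hierarchical levels separated."""

    spec: RegressionSpec
    coef_names: list
    conditions: list
    participants: list
    group_mu: np.ndarray    # (chains, draws, C, J)
    group_sd: np.ndarray    # (chains, draws, C, J)
    part: np.ndarray        # (chains, draws, P, C, J)
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.group_mu.shape[0]

    @property
    def n_draws(self) -> int:
        return self.group_mu.shape[1]

    def group_param_names(self) -> list:
        names = []
        for kind in ("mu", "sd"):
            for c in self.conditions:
                for j in self.coef_names:
                    names.append(f"{kind}_{j}({c})")
        return names

    def group_draws(self, name: str, condition: str, kind: str = "mu",
                    pooled: bool = True) -> np.ndarray:
        """Draws of a group-level parameter, pooled across chains by default.

        ``kind`` is "mu" (group mean, the default meaning of a bare
        coefficient name) or "sd".
        """
        if name not in self.coef_names:
            raise KeyError(f"unknown coefficient {name!r}; have {self.coef_names}")
        if condition not in self.conditions:
            raise KeyError(f"unknown condition {condition!r}; have {self.conditions}")
        j = self.coef_names.index(name)
        c = self.conditions.index(condition)
        arr = {"mu": self.group_mu, "sd": self.group_sd}[kind][:, :, c, j]
        return arr.reshape(-1) if pooled else arr


def _truncnorm_draw(rng, mean: float, sd: float, lo: float, hi: float) -> float:
    a = ndtr((lo - mean) / sd)
    b = ndtr((hi - mean) / sd)
    if b - a < 1e-12:  # numerically degenerate: clamp
        return min(max(mean, lo), hi)
    u = rng.uniform(a, b)
    return mean + sd * ndtri(u)


def _normal_logpdf_sum(x: np.ndarray, mu: float, sd: float) -> float:
    return float(-0.5 * np.sum(((x - mu) / sd) ** 2)
                 - x.size * (math.log(sd) + 0.5 * math.log(2 * math.pi)))


def _gibbs_group_sd(rng, vals: np.ndarray, mu: float, cur_sd: float,
                    rw_scale: float) -> float:
    """Sample the group sd from its conditional, truncated to its box.

    With a uniform prior on sd, the conditional of sd^2 given the
    participant values is inverse-gamma((P-1)/2, S/2); sampled exactly via
    inverse-CDF.  Falls back to a log-scale random walk when P < 2.
    """
    P = vals.size
    S = float(np.sum((vals - mu) ** 2))
    lo, hi = _SD_BOX
    if P >= 2 and S > 1e-12:
        # inv-gamma CDF(x) = gammaincc(shape, scale/x); inverted analytically
        shape = (P - 1) / 2.0
        scale = S / 2.0
        a = float(gammaincc(shape, scale / lo ** 2))
        b = float(gammaincc(shape, scale / hi ** 2))
        if b - a < 1e-14:
            return float(min(max(math.sqrt(S / P), lo), hi))
        u = rng.uniform(a, b)
        var = scale / float(gammainccinv(shape, u))
        return float(math.sqrt(var))
    prop = cur_sd * math.exp(rw_scale * rng.standard_normal())
    if lo <= prop <= hi:
        logr = (_normal_logpdf_sum(vals, mu, prop)
                - _normal_logpdf_sum(vals, mu, cur_sd)
                + math.log(prop) - math.log(cur_sd))
        if logr >= 0 or rng.random() < math.exp(logr):
            return float(prop)
    return float(cur_sd)


@njit(cache=True)
def _update_block(rt, acc, Xd, Xn, Xb, kd, kn, theta, cur_ll, mu, sd, boxes,
                  scales, normals, unifs, accepted, eps):
    """One Metropolis sweep over all coefficients of one block (in place).

    ``normals``/``unifs`` are pre-drawn so the host rng controls all
    randomness; returns the updated block log likelihood.
    """
    J = theta.shape[0]
    ll = cur_ll
    for j in range(J):
        cur = theta[j]
        prop = cur + scales[j] * normals[j]
        if prop < boxes[j, 0] or prop > boxes[j, 1]:
            accepted[j] = 0
            continue
        theta[j] = prop
        new_ll = _block_loglik_nb(rt, acc, Xd, Xn, Xb, theta[:kd],
                                  theta[kd:kd + kn], theta[kd + kn:], eps)
        ok = False
        if new_ll > -np.inf:
            dprior = (-0.5 * ((prop - mu[j]) / sd[j]) ** 2
                      + 0.5 * ((cur - mu[j]) / sd[j]) ** 2)
            logr = new_ll - ll + dprior
            if logr >= 0.0 or unifs[j] < math.exp(logr):
                ll = new_ll
                ok = True
        if ok:
            accepted[j] = 1
        else:
            theta[j] = cur
            accepted[j] = 0
    return ll


def _init_state(blocks, boxes, kd, kn, rng):
    """Finite-likelihood starting point, jittered per chain for dispersion."""
    J = boxes.shape[0]
    theta = {}
    for b in blocks:
        th = np.zeros(J)
        th[0] = 0.5 + 0.5 * rng.standard_normal()           # drift intercept
        ndt0 = 0.4 * float(np.min(b.rt)) * (0.8 + 0.3 * rng.random())
        th[kd] = max(ndt0, boxes[kd, 0] + 1e-3)
        th[kd + kn] = 1.5 + 0.4 * abs(rng.standard_normal())  # boundary
        th = np.clip(th, boxes[:, 0] + 1e-6, boxes[:, 1] - 1e-6)
        ll = block_loglik(b, th, kd, kn)
        tries = 0
        while not np.isfinite(ll) and tries < 40:
            th[kd] *= 0.7                                    # shrink ndt
            th[kd + kn] = min(th[kd + kn] * 1.2, boxes[kd + kn, 1] - 1e-6)
            ll = block_loglik(b, th, kd, kn)
            tries += 1
        if not np.isfinite(ll):
            raise RuntimeError(
                f"could not initialize block p={b.participant} c={b.condition}")
        theta[(b.participant, b.condition)] = (th, ll)
    return theta


def sample_posterior(table: pd.DataFrame, spec: RegressionSpec,
                     chains: int = 3, n: int = 5500, burn: int = 500,
                     thin: int = 50, seed: int = 0,
                     eps: float = 1e-7) -> PosteriorSamples:
    """Sample the joint posterior of group- and participant-level parameters.

    Defaults mirror the reference sampling settings (3 chains, 5500
    iterations, 500 burn-in, thinning 50).  Fully deterministic given
    ``seed``.
    """
    if burn >= n:
        raise ValueError("burn must be < n")
    if thin < 1:
        raise ValueError("thin must be >= 1")
    blocks = build_blocks(table, spec)
    conditions = sorted(table["condition"].unique().tolist())
    participants = sorted(table["participant"].unique().tolist())
    have = {(b.participant, b.condition) for b in blocks}
    for p in participants:
        for c in conditions:
            if (p, c) not in have:
                raise ValueError(f"missing trials for participant {p}, condition {c}")
    block_map = {(b.participant, b.condition): b for b in blocks}

    kd, kn, kb = len(spec.drift), len(spec.ndt), len(spec.boundary)
    J = kd + kn + kb
    C, P = len(conditions), len(participants)
    boxes = _coef_boxes(spec, float(np.quantile(table["rt"], 0.9)))
    coef_names = spec.all_coef_names

    keep_iters = list(range(burn, n, thin))
    D = len(keep_iters)
    group_mu = np.empty((chains, D, C, J))
    group_sd = np.empty((chains, D, C, J))
    part = np.empty((chains, D, P, C, J))
    accept_rates = []

    for ch in range(chains):
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 7, ch)))
        state = _init_state(blocks, boxes, kd, kn, rng)
        theta = np.empty((P, C, J))
        ll = np.empty((P, C))
        for pi, p in enumerate(participants):
            for ci, c in enumerate(conditions):
                th, l = state[(p, c)]
                theta[pi, ci] = th
                ll[pi, ci] = l
        mu = theta.mean(axis=0)                      # (C, J)
        sd = np.full((C, J), 0.3)
        mu = np.clip(mu, boxes[:, 0], boxes[:, 1])

        scales = np.full((P, C, J), 0.1)
        sd_scales = np.full((C, J), 0.3)
        joint_scales = np.full((2, C, J), 0.3)   # [rescale, translate]
        joint_acc = np.zeros((2, C, J))
        joint_prop = np.zeros((2, C, J))
        acc_ct = np.zeros((P, C, J))
        prop_ct = np.zeros((P, C, J))
        total_acc = 0
        total_prop = 0
        keep_ptr = 0

        accepted = np.zeros(J, dtype=np.int8)
        for it in range(n):
            # participant-level Metropolis updates (numba-hot path)
            normals = rng.standard_normal((P, C, J))
            unifs = rng.random((P, C, J))
            for pi, p in enumerate(participants):
                for ci, c in enumerate(conditions):
                    b = block_map[(p, c)]
                    ll[pi, ci] = _update_block(
                        b.rt, b.acc, b.Xd, b.Xn, b.Xb, kd, kn,
                        theta[pi, ci], ll[pi, ci], mu[ci], sd[ci], boxes,
                        scales[pi, ci], normals[pi, ci], unifs[pi, ci],
                        accepted, eps)
                    acc_ct[pi, ci] += accepted
                    prop_ct[pi, ci] += 1
                    total_acc += int(accepted.sum())
                    total_prop += J

            # group-level updates
            for ci in range(C):
                for j in range(J):
                    vals = theta[:, ci, j]
                    # Gibbs for the group mean (truncated normal)
                    mu[ci, j] = _truncnorm_draw(rng, float(vals.mean()),
                                                sd[ci, j] / math.sqrt(P),
                                                boxes[j, 0], boxes[j, 1])
                    sd[ci, j] = _gibbs_group_sd(rng, vals, mu[ci, j],
                                                sd[ci, j], sd_scales[ci, j])

            # joint group moves, both applied every iteration:
            #  - rescale: scale the participant deviations and the group sd
            #    together (breaks the funnel coupling);
            #  - translate: shift the group mean and every participant value
            #    together (the ensemble's slow common-mode direction).
            for kind in (0, 1):  # 0 = rescale, 1 = translate
                for ci in range(C):
                    for j in range(J):
                        joint_prop[kind, ci, j] += 1
                        if kind == 0:
                            csc = math.exp(joint_scales[0, ci, j] * rng.standard_normal())
                            sd_new = sd[ci, j] * csc
                            mu_new = mu[ci, j]
                            if not _SD_BOX[0] <= sd_new <= _SD_BOX[1]:
                                continue
                            th_new = mu[ci, j] + csc * (theta[:, ci, j] - mu[ci, j])
                            log_jac = math.log(csc)  # c^(P+1) Jacobian vs c^-P prior
                        else:
                            delta = (joint_scales[1, ci, j] * sd[ci, j]
                                     * rng.standard_normal())
                            mu_new = mu[ci, j] + delta
                            sd_new = sd[ci, j]
                            if not boxes[j, 0] <= mu_new <= boxes[j, 1]:
                                continue
                            th_new = theta[:, ci, j] + delta
                            log_jac = 0.0  # prior deviations unchanged
                        if th_new.min() < boxes[j, 0] or th_new.max() > boxes[j, 1]:
                            continue
                        new_ll = np.empty(P)
                        ok = True
                        for pi, p in enumerate(participants):
                            b = block_map[(p, conditions[ci])]
                            tmp = theta[pi, ci].copy()
                            tmp[j] = th_new[pi]
                            l = block_loglik(b, tmp, kd, kn, eps)
                            if not np.isfinite(l):
                                ok = False
                                break
                            new_ll[pi] = l
                        if not ok:
                            continue
                        logr = float(new_ll.sum() - ll[:, ci].sum()) + log_jac
                        if logr >= 0 or rng.random() < math.exp(logr):
                            theta[:, ci, j] = th_new
                            ll[:, ci] = new_ll
                            sd[ci, j] = sd_new
                            mu[ci, j] = mu_new
                            joint_acc[kind, ci, j] += 1

            # proposal adaptation (burn-in only)
            if it < burn and (it + 1) % 50 == 0:
                rates = acc_ct / np.maximum(prop_ct, 1)
                scales *= np.exp(1.5 * (rates - 0.3))
                np.clip(scales, 1e-5, 10.0, out=scales)
                acc_ct[:] = 0
                prop_ct[:] = 0
                jrates = joint_acc / np.maximum(joint_prop, 1)
                joint_scales *= np.exp(1.5 * (jrates - 0.25))
                np.clip(joint_scales, 0.02, 5.0, out=joint_scales)
                joint_acc[:] = 0
                joint_prop[:] = 0

            if keep_ptr < D and it == keep_iters[keep_ptr]:
                group_mu[ch, keep_ptr] = mu
                group_sd[ch, keep_ptr] = sd
                part[ch, keep_ptr] = theta
                keep_ptr += 1

        accept_rates.append(total_acc / max(total_prop, 1))

    meta = {"chains": chains, "n": n, "burn": burn, "thin": thin, "seed": seed,
            "acceptance": accept_rates, "kd": kd, "kn": kn, "kb": kb}
    return PosteriorSamples(spec=spec, coef_names=coef_names,
                            conditions=conditions, participants=participants,
                            group_mu=group_mu, group_sd=group_sd, part=part,
                            meta=meta)


def gelman_rubin(samples: PosteriorSamples) -> dict:
    """Potential-scale-reduction factor for every group-level parameter."""
    if samples.n_chains < 2:
        raise ValueError("Gelman-Rubin needs >= 2 chains")
    if samples.n_draws < 10:
        raise ValueError("need >= 10 retained draws per chain")
    out = {}
    for kind, arr in (("mu", samples.group_mu), ("sd", samples.group_sd)):
        for ci, c in enumerate(samples.conditions):
            for j, name in enumerate(samples.coef_names):
                out[f"{kind}_{name}({c})"] = _psrf(arr[:, :, ci, j])
    return out


def _psrf(draws: np.ndarray) -> float:
    """Classic PSRF from an (m chains, n draws) array."""
    m, n = draws.shape
    W = float(np.mean(np.var(draws, axis=1, ddof=1)))
    B_over_n = float(np.var(np.mean(draws, axis=1), ddof=1))
    if W <= 0:
        return 1.0
    v_hat = (n - 1) / n * W + (1.0 + 1.0 / m) * B_over_n
    return float(np.sqrt(v_hat / W))


_EXPR_TOKEN = re.compile(r"([A-Za-z_]\w*)\(([^)]+)\)")


def posterior_prob(samples: PosteriorSamples, expression) -> float:
    """Fraction of pooled draws satisfying an expression of group means.

    String expressions reference parameters as ``name(condition)``, e.g.
    ``"gamma1(VH) > gamma1(V)"`` or ``"gamma1(VH) - gamma1(V) > 0"``;
    ``sd_name(condition)`` addresses a group standard deviation.  A callable
    receives the samples object and must return a boolean array.
    """
    if callable(expression):
        vals = np.asarray(expression(samples))
        return float(np.mean(vals))
    env: dict[str, np.ndarray] = {}

    def _sub(match: re.Match) -> str:
        name, cond = match.group(1), match.group(2).strip()
        kind = "mu"
        if name.startswith("sd_"):
            kind, name = "sd", name[3:]
        var = f"_{kind}_{name}_{cond}".replace("-", "_")
        env[var] = samples.group_draws(name, cond, kind=kind)
        return var

    expr = _EXPR_TOKEN.sub(_sub, str(expression))
    vals = eval(expr, {"__builtins__": {}}, env)  # noqa: S307 - restricted env
    vals = np.asarray(vals)
    if vals.dtype != bool:
        raise ValueError("expression must be a comparison")
    return float(np.mean(vals))


@dataclass
class DICResult:
    dic: float
    mean_deviance: float
    deviance_at_mean: float
    p_d: float


def dic(samples: PosteriorSamples, table: pd.DataFrame,
        spec: RegressionSpec | None = None, eps: float = 1e-7) -> DICResult:
    """Deviance information criterion: DIC = D_bar + pD, focused on the
    participant-level parameters (lower is better)."""
    spec = spec or samples.spec
    blocks = build_blocks(table, spec)
    block_map = {(b.participant, b.condition): b for b in blocks}
    kd, kn = samples.meta["kd"], samples.meta["kn"]
    C_ = samples.conditions
    P_ = samples.participants

    flat = samples.part.reshape(-1, len(P_), len(C_), samples.part.shape[-1])
    devs = np.empty(flat.shape[0])
    for d in range(flat.shape[0]):
        total = 0.0
        for pi, p in enumerate(P_):
            for ci, c in enumerate(C_):
                total += block_loglik(block_map[(p, c)], flat[d, pi, ci], kd, kn, eps)
        devs[d] = -2.0 * total
    if not np.all(np.isfinite(devs)):
        raise FloatingPointError("non-finite deviance at a retained draw")

    theta_bar = flat.mean(axis=0)
    total = 0.0
    for pi, p in enumerate(P_):
        for ci, c in enumerate(C_):
            total += block_loglik(block_map[(p, c)], theta_bar[pi, ci], kd, kn, eps)
    d_hat = -2.0 * total
    if not np.isfinite(d_hat):
        raise FloatingPointError("likelihood is zero at the posterior mean")
    d_bar = float(devs.mean())
    p_d = d_bar - d_hat
    return DICResult(dic=d_bar + p_d, mean_deviance=d_bar,
                     deviance_at_mean=d_hat, p_d=p_d)


def summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Mean, 5%/95% quantiles and R-hat for every group-level parameter."""
    rhat = gelman_rubin(samples)
    rows = []
    for kind, arr in (("mu", samples.group_mu), ("sd", samples.group_sd)):
        for ci, c in enumerate(samples.conditions):
            for j, name in enumerate(samples.coef_names):
                pooled = arr[:, :, ci, j].reshape(-1)
                key = f"{kind}_{name}({c})"
                rows.append({
                    "parameter": key,
                    "mean": float(pooled.mean()),
                    "ci_5": float(np.quantile(pooled, 0.05)),
                    "ci_95": float(np.quantile(pooled, 0.95)),
                    "r_hat": rhat[key],
                })
    return pd.DataFrame(rows)
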