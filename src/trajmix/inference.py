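"""MAP-penalized EM fitting of the mixture families, and model evidence.

The penalized objective maximized by EM is

    sum_i log sum_c pi_c P(panel_i | c)
      + alpha * sum_c log pi_c                       (class-weight pseudocounts)
      - (precision / 2) * sum(theta^2)               (probit-score prior)

where ``theta = ndtri(p)`` for every emission/initial/transition
probability. Both prior terms have closed-form or concave-1D exact
M-steps, so the trace is non-decreasing up to solver tolerance.

Missing cells never get imputed: the E-step marginalizes them exactly
(see :mod:`trajmix.latent_models`), and for the Markov families expected
transition counts come from a forward-backward pass over the joint
symptom configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, logsumexp, ndtr, ndtri

from trajmix import latent_models
from trajmix.latent_models import (
    LOG_FLOOR,
    ModelParams,
    ModelSpec,
    _clip,
    _markov_forward,
    joint_transition_matrices,
    loglik_matrix,
    parent_symptoms,
    state_bits,
    trans_shapes,
)
from trajmix.synthetic_cohort import CohortTable

WEIGHT_FLOOR = 1e-10


@dataclass
class FitConfig:
    """Optimization settings; ``seed`` drives every source of randomness."""

    seed: int
    restarts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    window: int = 100  # objective must be stable for this many iterations


@dataclass
class FitResult:
    params: ModelParams
    membership: np.ndarray  # (N, n) posterior class probabilities
    assignment: np.ndarray  # (N,) argmax class
    evidence: float  # final penalized objective of the winning restart
    trace: list[float] = field(default_factory=list)
    seed: int = 0
    restarts: int = 1
    converged: bool = False
    spec: ModelSpec | None = None

    def membership_frame(self, child_id: np.ndarray):
        import pandas as pd

        n = self.membership.shape[1]
        frame = pd.DataFrame(
            self.membership, columns=[f"p_class_{c + 1}" for c in range(n)]
        )
        frame.insert(0, "child_id", child_id)
        frame["assigned_class"] = self.assignment
        return frame


def objective_stable(trace, window: int, rtol: float) -> bool:
    """True iff the last ``window`` objective values vary by < rtol (relative)."""
    if len(trace) < window:
        return False
    tail = np.asarray(trace[-window:], dtype=float)
    scale = max(1.0, float(np.abs(tail[-1])))
    return float(tail.max() - tail.min()) < rtol * scale


# ---------------------------------------------------------------------------
# probit MAP solver
# ---------------------------------------------------------------------------


def probit_map(a: np.ndarray, b: np.ndarray, precision: float = 1.0) -> np.ndarray:
    """argmax_theta  a*log Phi + b*log(1 - Phi) - precision*theta^2/2, as Phi(theta).

    ``a``/``b`` are (possibly fractional) success/failure counts. The
    objective is strictly concave, so damped Newton converges; the result
    is returned on the probability scale, clamped away from 0/1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    theta = ndtri(np.clip((a + 1.0) / (a + b + 2.0), 1e-6, 1 - 1e-6))
    for _ in range(80):
        logphi = -0.5 * theta**2 - 0.5 * np.log(2 * np.pi)
        r1 = np.exp(logphi - log_ndtr(theta))  # phi / Phi
        r0 = np.exp(logphi - log_ndtr(-theta))  # phi / (1 - Phi)
        g = a * r1 - b * r0 - precision * theta
        h = -a * (theta * r1 + r1**2) + b * (theta * r0 - r0**2) - precision
        step = np.clip(g / h, -4.0, 4.0)
        theta = theta - step
        if np.max(np.abs(g)) < 1e-10 * (1.0 + np.max(a + b)):
            break
    return _clip(ndtr(theta))


# ---------------------------------------------------------------------------
# EM
# ---------------------------------------------------------------------------


def _penalized_objective(ll: np.ndarray, params: ModelParams, spec: ModelSpec) -> float:
    logw = np.log(np.clip(params.weights, WEIGHT_FLOOR, None))
    data = float(logsumexp(ll + logw[None, :], axis=1).sum())
    prior_w = float(spec.dirichlet_pseudocount * logw.sum())
    prior_theta = params.probit_penalty(
        precision=spec.emission_prior_precision, mean=spec.emission_prior_mean
    )
    return data + prior_w + prior_theta


def _responsibilities(ll: np.ndarray, weights: np.ndarray) -> np.ndarray:
    logw = np.log(np.clip(weights, WEIGHT_FLOOR, None))
    lp = ll + logw[None, :]
    lp -= lp.max(axis=1, keepdims=True)
    r = np.exp(lp)
    r /= r.sum(axis=1, keepdims=True)
    return r


def _mstep_weights(r: np.ndarray, alpha: float) -> np.ndarray:
    counts = r.sum(axis=0) + alpha
    w = np.clip(counts, WEIGHT_FLOOR, None)
    return w / w.sum()


def _mstep_latent_profile(
    y: np.ndarray, mask: np.ndarray, r: np.ndarray, precision: float
) -> np.ndarray:
    pos = (mask & (y == 1)).astype(float)
    neg = (mask & (y == 0)).astype(float)
    a = np.einsum("ic,ist->cst", r, pos)
    b = np.einsum("ic,ist->cst", r, neg)
    return probit_map(a, b, precision=precision)


def _mstep_markov(
    y: np.ndarray, mask: np.ndarray, r: np.ndarray, params: ModelParams, precision: float
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Expected-count M-step via forward-backward on the joint state chain."""
    N, S, T = y.shape
    n = params.n_classes
    K = 2**S
    bits = state_bits(S).astype(float)  # (K, S)
    parents = parent_symptoms(params.family, S)
    _, alphas, _, cons = _markov_forward(y, mask, params)
    tmats = joint_transition_matrices(params)

    a_init = np.zeros((n, S))
    b_init = np.zeros((n, S))
    shapes = trans_shapes(params.family, n, S, T)
    a_tr = [np.zeros(sh) for sh in shapes]
    b_tr = [np.zeros(sh) for sh in shapes]
    cfg_idx = [
        np.array(
            [sum((int(bits[k, p]) << j) for j, p in enumerate(parents[s])) for k in range(K)]
        )
        for s in range(S)
    ]

    for c in range(n):
        w = r[:, c]
        # backward pass (scaled)
        beta = np.ones((N, K))
        betas = [None] * T
        betas[T - 1] = beta
        for t in range(T - 2, -1, -1):
            beta = (betas[t + 1] * cons[t + 1]) @ tmats[c, t].T
            z = beta.sum(axis=1, keepdims=True)
            z[z <= 0] = 1.0
            betas[t] = beta / z
        # initial-state marginal
        g0 = alphas[c, 0] * betas[0]
        z = g0.sum(axis=1, keepdims=True)
        z[z <= 0] = 1.0
        g0 /= z
        occ = (w[:, None] * g0).sum(axis=0)  # (K,)
        a_init[c] = occ @ bits
        b_init[c] = occ @ (1.0 - bits)
        # pairwise transition marginals
        for t in range(1, T):
            right = betas[t] * cons[t]  # (N, K)
            xi = alphas[c, t - 1][:, :, None] * tmats[c, t - 1][None, :, :] * right[:, None, :]
            z = xi.sum(axis=(1, 2))
            z[z <= 0] = 1.0
            X = np.einsum("i,ikl->kl", w / z, xi)  # (K, K) expected counts
            for s in range(S):
                # collapse prev state to parent config, next state to target bit
                pos = X[:, bits[:, s] == 1].sum(axis=1)
                neg = X[:, bits[:, s] == 0].sum(axis=1)
                np.add.at(a_tr[s][c, t - 1], cfg_idx[s], pos)
                np.add.at(b_tr[s][c, t - 1], cfg_idx[s], neg)

    init = probit_map(a_init, b_init, precision=precision)
    trans = [probit_map(a, b, precision=precision) for a, b in zip(a_tr, b_tr)]
    return init, trans


def _em(
    y: np.ndarray,
    mask: np.ndarray,
    spec: ModelSpec,
    params: ModelParams,
    config: FitConfig,
) -> tuple[ModelParams, np.ndarray, list[float], bool]:
    trace: list[float] = []
    precision = spec.emission_prior_precision
    r = None
    for _ in range(config.max_iter):
        ll = loglik_matrix(y, mask, params)
        trace.append(_penalized_objective(ll, params, spec))
        r = _responsibilities(ll, params.weights)
        weights = _mstep_weights(r, spec.dirichlet_pseudocount)
        if spec.family == "latent_profile":
            emit = _mstep_latent_profile(y, mask, r, precision)
            params = ModelParams(spec.family, weights, emit=emit)
        else:
            init, trans = _mstep_markov(y, mask, r, params, precision)
            params = ModelParams(spec.family, weights, init=init, trans=trans)
        if objective_stable(trace, config.window, config.tol):
            break
    ll = loglik_matrix(y, mask, params)
    trace.append(_penalized_objective(ll, params, spec))
    r = _responsibilities(ll, params.weights)
    converged = objective_stable(trace, config.window, config.tol)
    return params, r, trace, converged


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def _init_params(
    y: np.ndarray,
    mask: np.ndarray,
    spec: ModelSpec,
    rng: np.random.Generator,
    kmeans_style: bool,
) -> ModelParams:
    """Responsibilities -> one M-step. Even restarts use a k-means-style
    seeding on zero-centred imputed panels; odd restarts use random soft
    assignments."""
    N = y.shape[0]
    n = spec.n_classes
    if kmeans_style:
        flat = np.where(mask, y.astype(float), 0.5).reshape(N, -1)
        # k-means++ seeding so small well-separated clusters get a center
        centers = [flat[rng.integers(N)]]
        d2 = ((flat - centers[0]) ** 2).sum(axis=1)
        for _ in range(1, min(n, N)):
            tot = d2.sum()
            if tot <= 0:
                centers.append(flat[rng.integers(N)])
                continue
            pick = rng.choice(N, p=d2 / tot)
            centers.append(flat[pick])
            d2 = np.minimum(d2, ((flat - centers[-1]) ** 2).sum(axis=1))
        centers = np.array(centers)
        if len(centers) < n:  # more classes than children
            centers = np.vstack([centers, rng.random((n - len(centers), flat.shape[1]))])
        for _ in range(10):
            d = ((flat[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            lab = d.argmin(axis=1)
            for c in range(n):
                sel = lab == c
                if sel.any():
                    centers[c] = flat[sel].mean(axis=0)
        r = np.full((N, n), 0.05 / max(n - 1, 1))
        r[np.arange(N), lab] = 0.95
        r /= r.sum(axis=1, keepdims=True)
    else:
        r = rng.dirichlet(np.ones(n), size=N)
    weights = _mstep_weights(r, spec.dirichlet_pseudocount)
    precision = spec.emission_prior_precision
    if spec.family == "latent_profile":
        emit = _mstep_latent_profile(y, mask, r, precision)
        return ModelParams(spec.family, weights, emit=emit)
    # Markov families: moment-match init/transition tables from hard-ish counts
    S, T = y.shape[1], y.shape[2]
    parents = parent_symptoms(spec.family, S)
    pos0 = (mask[:, :, 0] & (y[:, :, 0] == 1)).astype(float)
    neg0 = (mask[:, :, 0] & (y[:, :, 0] == 0)).astype(float)
    init = probit_map(r.T @ pos0, r.T @ neg0, precision=precision)
    trans = []
    for s in range(S):
        n_cfg = 2 ** len(parents[s])
        a = np.zeros((n, T - 1, n_cfg))
        b = np.zeros((n, T - 1, n_cfg))
        for t in range(1, T):
            obs_t = mask[:, s, t] & mask[:, parents[s], t - 1].all(axis=1)
            cfg = np.zeros(N, dtype=np.int64)
            for j, p in enumerate(parents[s]):
                cfg += y[:, p, t - 1].astype(np.int64) << j
            for q in range(n_cfg):
                sel = obs_t & (cfg == q)
                a[:, t - 1, q] = r[sel].T @ (y[sel, s, t] == 1)
                b[:, t - 1, q] = r[sel].T @ (y[sel, s, t] == 0)
        trans.append(probit_map(a, b, precision=precision))
    return ModelParams(spec.family, init=init, trans=trans, weights=weights)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _panel_arrays(cohort) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(cohort, CohortTable):
        return cohort.y, cohort.y_mask
    y, mask = cohort
    return np.asarray(y, dtype=np.int8), np.asarray(mask, dtype=bool)


def fit(cohort, spec: ModelSpec, config: FitConfig) -> FitResult:
    """Best-of-restarts EM fit; deterministic given ``config.seed``.

    ``cohort`` is a CohortTable or a ``(y, mask)`` pair of (N, S, T)
    arrays. Ties between restarts break towards the lowest restart index.
    """
    y, mask = _panel_arrays(cohort)
    n_distinct = len({(row.tobytes(), m.tobytes()) for row, m in zip(y, mask)})
    if spec.n_classes > n_distinct:
        warnings.warn(
            f"n_classes={spec.n_classes} exceeds the {n_distinct} distinct observed panels; "
            "some classes may come back empty",
            stacklevel=2,
        )
    best = None
    for restart in range(max(config.restarts, 1)):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, restart]))
        params0 = _init_params(y, mask, spec, rng, kmeans_style=restart % 2 == 0)
        params, r, trace, converged = _em(y, mask, spec, params0, config)
        if best is None or trace[-1] > best[2][-1] + 1e-12:
            best = (params, r, trace, converged)
    params, r, trace, converged = best
    if not converged:
        warnings.warn("EM did not meet the stability rule; returning best fit anyway", stacklevel=2)
    return FitResult(
        params=params,
        membership=r,
        assignment=r.argmax(axis=1),
        evidence=trace[-1],
        trace=trace,
        seed=config.seed,
        restarts=config.restarts,
        converged=converged,
        spec=spec,
    )


def posterior_membership(y, mask, params: ModelParams, spec: ModelSpec | None = None) -> np.ndarray:
    """P(class | panel) for one (S, T) panel; uniform (with a warning) if
    every class is at the likelihood floor."""
    ll = loglik_matrix(np.asarray(y)[None], np.asarray(mask, dtype=bool)[None], params)[0]
    if np.all(ll <= LOG_FLOOR):
        warnings.warn("panel impossible under every class; returning uniform membership", stacklevel=2)
        return np.full(params.n_classes, 1.0 / params.n_classes)
    logw = np.log(np.clip(params.weights, WEIGHT_FLOOR, None))
    lp = ll + logw
    lp -= lp.max()
    p = np.exp(lp)
    return p / p.sum()


def _holdout_splits(n: int, n_splits: int, frac: float, seed: int):
    """Deterministic holdout index sets, derived only from (seed, n)."""
    n_hold = max(1, int(round(frac * n)))
    if n_hold >= n:
        raise ValueError("holdout fraction leaves an empty training set")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n]))
    for _ in range(n_splits):
        perm = rng.permutation(n)
        yield perm[:n_hold], perm[n_hold:]


def evidence(
    cohort,
    spec: ModelSpec,
    config: FitConfig,
    method: str = "holdout",
    n_splits: int = 100,
    holdout_frac: float = 0.1,
) -> float:
    """Model-comparison score, higher is better.

    ``holdout``: mean per-child predictive log-likelihood over ``n_splits``
    random train/holdout splits (fraction ``holdout_frac`` held out). The
    splits are derived from (config.seed, N) after sorting children by id,
    so the score does not depend on row order. ``bic``: in-sample
    log-likelihood minus the BIC penalty ``k/2 * log N``.
    """
    y, mask = _panel_arrays(cohort)
    if isinstance(cohort, CohortTable):
        order = np.argsort(cohort.child_id, kind="stable")
        y, mask = y[order], mask[order]
    n = y.shape[0]
    if method == "bic":
        res = fit((y, mask), spec, config)
        ll = loglik_matrix(y, mask, res.params)
        logw = np.log(np.clip(res.params.weights, WEIGHT_FLOOR, None))
        data_ll = float(logsumexp(ll + logw[None, :], axis=1).sum())
        return data_ll - 0.5 * res.params.n_parameters() * np.log(n)
    if method != "holdout":
        raise ValueError(f"unknown evidence method {method!r}")
    scores = []
    for i, (hold, train) in enumerate(_holdout_splits(n, n_splits, holdout_frac, config.seed)):
        split_cfg = FitConfig(
            seed=int(np.random.SeedSequence([config.seed, 1000 + i]).generate_state(1)[0] % 2**31),
            restarts=config.restarts,
            max_iter=config.max_iter,
            tol=config.tol,
            window=config.window,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit((y[train], mask[train]), spec, split_cfg)
        ll = loglik_matrix(y[hold], mask[hold], res.params)
        logw = np.log(np.clip(res.params.weights, WEIGHT_FLOOR, None))
        scores.append(float(logsumexp(ll + logw[None, :], axis=1).mean()))
    return float(np.mean(scores))
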