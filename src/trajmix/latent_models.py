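"""Model families: parameter spaces, likelihoods, and sampling.

Three generative families over a child's panel ``y[s, t]`` of binary
indicators (S symptoms x T ages), all mixed over ``n`` latent classes:

* ``independent_markov``: given the class, each symptom follows its own
  first-order chain over the age grid.
* ``atopic_march_markov``: first-order chains with additional lagged
  cross-symptom parents — eczema(t-1) conditions wheeze(t), and
  wheeze(t-1) conditions rhinitis(t).
* ``latent_profile``: given the class, every cell is an independent
  Bernoulli draw with its own emission probability.

Emission/transition probabilities live on the probit scale
(``p = Phi(theta)``) with a standard-normal prior on ``theta``; the
probability-scale arrays stored in :class:`ModelParams` are the primary
representation and the probit score is recovered with ``ndtri`` where the
prior penalty is needed.

Missing cells are handled by exact marginalization: for the Markov
families the joint symptom state at each age is a single categorical
variable over ``2**S`` configurations, and a forward pass sums over every
configuration consistent with the observed cells.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtri

FAMILIES = ("independent_markov", "atopic_march_markov", "latent_profile")

#: Canonical symptom order for the Markov families.
MARKOV_SYMPTOMS = ("eczema", "wheeze", "rhinitis")

#: Floor applied to impossible (zero-probability) panels so optimization
#: stays finite.
LOG_FLOOR = -1e12

#: Probabilities are clamped to [PROB_EPS, 1 - PROB_EPS].
PROB_EPS = 1e-4


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


@dataclass(frozen=True)
class ModelSpec:
    """Family, class count and prior hyperparameters of a mixture model."""

    family: str
    n_classes: int
    dirichlet_pseudocount: float = 1.0
    emission_prior_mean: float = 0.0
    emission_prior_precision: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if self.dirichlet_pseudocount <= 0:
            raise ValueError("dirichlet_pseudocount must be > 0")
        if self.emission_prior_precision < 0:
            raise ValueError("emission_prior_precision must be >= 0")


def parent_symptoms(family: str, n_symptoms: int) -> list[list[int]]:
    """Lag-1 parent symptom indices for each symptom, per family.

    All parents live at the previous time step; ``parent_symptoms(...)[s]``
    lists the symptom indices whose value at ``t - 1`` conditions symptom
    ``s`` at ``t``. Element 0 of each list is the symptom's own history
    where present.
    """
    if family == "independent_markov":
        return [[s] for s in range(n_symptoms)]
    if family == "atopic_march_markov":
        if n_symptoms != 3:
            raise ValueError("atopic_march_markov is defined for exactly 3 symptoms")
        # eczema <- eczema; wheeze <- wheeze, eczema; rhinitis <- rhinitis, wheeze
        return [[0], [1, 0], [2, 1]]
    raise ValueError(f"family {family!r} has no Markov parent structure")


def atopic_march_parents(symptom: str, t: int) -> set[tuple[str, int]]:
    """Parent cells of ``(symptom, t)`` in the cross-symptom march family.

    ``t`` is a 1-based position on the age grid; ``t == 1`` is the chain
    start and has no parents.
    """
    if symptom not in MARKOV_SYMPTOMS:
        raise ValueError(f"unknown symptom {symptom!r}")
    if t < 1:
        raise ValueError("t must be >= 1")
    if t == 1:
        return set()
    idx = MARKOV_SYMPTOMS.index(symptom)
    return {(MARKOV_SYMPTOMS[p], t - 1) for p in parent_symptoms("atopic_march_markov", 3)[idx]}


@dataclass
class ModelParams:
    """Mixture weights plus family-specific emission/transition tables.

    For ``latent_profile`` only ``emit`` is set, shaped ``(n, S, T)``.
    For the Markov families ``init`` is ``(n, S)`` — P(symptom present at
    the first age) — and ``trans[s]`` is ``(n, T - 1, 2**k_s)`` where
    ``k_s`` is the number of lag-1 parents of symptom ``s``; the last axis
    is indexed by the parent configuration (parent ``j``'s bit is
    ``1 << j`` in the order given by :func:`parent_symptoms`).
    """

    family: str
    weights: np.ndarray
    emit: np.ndarray | None = None
    init: np.ndarray | None = None
    trans: list[np.ndarray] | None = None

    @property
    def n_classes(self) -> int:
        return len(self.weights)

    @property
    def shape(self) -> tuple[int, int]:
        """(S, T) of the panels this parameter set describes."""
        if self.family == "latent_profile":
            return self.emit.shape[1], self.emit.shape[2]
        return self.init.shape[1], self.trans[0].shape[1] + 1

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
            raise ValueError("weights must be a probability vector")
        arrays = [self.emit] if self.family == "latent_profile" else [self.init, *self.trans]
        for arr in arrays:
            if arr is None:
                raise ValueError(f"missing parameter arrays for family {self.family!r}")
            if np.any((arr < 0) | (arr > 1)):
                raise ValueError("probabilities must lie in [0, 1]")

    def n_parameters(self) -> int:
        """Count of free parameters (weights contribute n - 1)."""
        n = self.n_classes - 1
        if self.family == "latent_profile":
            n += self.emit.size
        else:
            n += self.init.size + sum(a.size for a in self.trans)
        return n

    def probit_penalty(self, precision: float = 1.0, mean: float = 0.0) -> float:
        """Log-density kernel of the N(mean, 1/precision) probit prior."""
        if precision == 0:
            return 0.0
        arrays = [self.emit] if self.family == "latent_profile" else [self.init, *self.trans]
        total = 0.0
        for arr in arrays:
            theta = ndtri(_clip(np.asarray(arr, dtype=float)))
            total -= 0.5 * precision * float(np.sum((theta - mean) ** 2))
        return total

    def to_json(self) -> str:
        payload: dict = {"family": self.family, "weights": self.weights.tolist()}
        if self.family == "latent_profile":
            payload["emit"] = self.emit.tolist()
        else:
            payload["init"] = self.init.tolist()
            payload["trans"] = [a.tolist() for a in self.trans]
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        payload = json.loads(text)
        family = payload["family"]
        weights = np.asarray(payload["weights"], dtype=float)
        if family == "latent_profile":
            return cls(family, weights, emit=np.asarray(payload["emit"], dtype=float))
        return cls(
            family,
            weights,
            init=np.asarray(payload["init"], dtype=float),
            trans=[np.asarray(a, dtype=float) for a in payload["trans"]],
        )


# ---------------------------------------------------------------------------
# joint-state machinery for the Markov families
# ---------------------------------------------------------------------------


def state_bits(n_symptoms: int) -> np.ndarray:
    """(2**S, S) table: bit of symptom ``s`` in each joint configuration."""
    k = 2**n_symptoms
    states = np.arange(k)
    return ((states[:, None] >> np.arange(n_symptoms)[None, :]) & 1).astype(np.int8)


def _parent_config_index(bits: np.ndarray, parents: Sequence[int]) -> np.ndarray:
    """Map each joint state to its parent-configuration index for one symptom."""
    idx = np.zeros(bits.shape[0], dtype=np.int64)
    for j, p in enumerate(parents):
        idx += bits[:, p].astype(np.int64) << j
    return idx


def initial_state_probs(params: ModelParams) -> np.ndarray:
    """(n, K) joint distribution over symptom configurations at the first age."""
    S = params.init.shape[1]
    bits = state_bits(S)  # (K, S)
    p = params.init  # (n, S)
    # prod over symptoms of p^bit (1-p)^(1-bit)
    probs = np.where(bits[None, :, :] == 1, p[:, None, :], 1.0 - p[:, None, :])
    return probs.prod(axis=2)


def joint_transition_matrices(params: ModelParams) -> np.ndarray:
    """(n, T-1, K, K) transition matrices over joint symptom configurations."""
    n, S = params.init.shape
    T = params.trans[0].shape[1] + 1
    K = 2**S
    bits = state_bits(S)
    parents = parent_symptoms(params.family, S)
    out = np.ones((n, T - 1, K, K))
    for s in range(S):
        cfg = _parent_config_index(bits, parents[s])  # (K,) config of prev state
        p = params.trans[s][:, :, cfg]  # (n, T-1, K) P(y_s=1 | prev state)
        bit = bits[:, s][None, None, None, :]  # target bit of next state
        out *= np.where(bit == 1, p[:, :, :, None], 1.0 - p[:, :, :, None])
    return out


def _consistency_masks(y: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(T, N, K) indicator that joint state k agrees with the observed cells."""
    N, S, T = y.shape
    bits = state_bits(S)  # (K, S)
    cons = np.ones((T, N, bits.shape[0]), dtype=bool)
    for t in range(T):
        obs = mask[:, :, t]  # (N, S)
        agree = (y[:, None, :, t] == bits[None, :, :]) | ~obs[:, None, :]
        cons[t] = agree.all(axis=2)
    return cons


def _markov_forward(
    y: np.ndarray, mask: np.ndarray, params: ModelParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward pass for every class.

    Returns ``(loglik, alphas, scales, cons)`` where ``loglik`` is (N, n),
    ``alphas`` is (n, T, N, K) scaled so each (child, t) slice sums to 1
    (or is uniform for dead children), ``scales`` (n, T, N) holds the
    per-step normalizers, and ``cons`` the (T, N, K) consistency masks.
    """
    N, S, T = y.shape
    n = params.n_classes
    K = 2**S
    cons = _consistency_masks(y, mask)
    pi0 = initial_state_probs(params)  # (n, K)
    tmats = joint_transition_matrices(params)  # (n, T-1, K, K)
    loglik = np.zeros((N, n))
    alphas = np.zeros((n, T, N, K))
    scales = np.zeros((n, T, N))
    for c in range(n):
        ll = np.zeros(N)
        a = pi0[c][None, :] * cons[0]
        for t in range(T):
            if t > 0:
                a = (a @ tmats[c, t - 1]) * cons[t]
            z = a.sum(axis=1)
            dead = z <= 0
            if dead.any():
                ll[dead] = LOG_FLOOR
                a[dead] = 1.0 / K
                z = np.where(dead, 1.0, z)
            live = ll > LOG_FLOOR
            ll[live] += np.log(z[live])
            a = a / z[:, None]
            alphas[c, t] = a
            scales[c, t] = z
        loglik[:, c] = ll
    return loglik, alphas, scales, cons


def loglik_matrix(y: np.ndarray, mask: np.ndarray, params: ModelParams) -> np.ndarray:
    """Class-conditional log-likelihood of each child's observed cells, (N, n)."""
    y = np.asarray(y, dtype=np.int8)
    mask = np.asarray(mask, dtype=bool)
    if params.family == "latent_profile":
        with np.errstate(divide="ignore"):
            lp = np.log(params.emit)
            lq = np.log1p(-params.emit)
        pos = (mask & (y == 1)).astype(float)
        neg = (mask & (y == 0)).astype(float)
        # xlogy semantics: an unobserved or non-matching cell contributes 0
        # even when the corresponding log term is -inf
        ll = np.einsum("ist,cst->ic", pos, np.where(np.isfinite(lp), lp, 0.0))
        ll += np.einsum("ist,cst->ic", neg, np.where(np.isfinite(lq), lq, 0.0))
        hit_pos = np.einsum("ist,cst->ic", pos, (~np.isfinite(lp)).astype(float))
        hit_neg = np.einsum("ist,cst->ic", neg, (~np.isfinite(lq)).astype(float))
        return np.where(hit_pos + hit_neg > 0, LOG_FLOOR, ll)
    return _markov_forward(y, mask, params)[0]


def complete_loglik(
    y: np.ndarray, mask: np.ndarray, c: int, params: ModelParams, spec: ModelSpec | None = None
) -> float:
    """Log P(observed cells | class c) for a single (S, T) panel.

    Missing cells — including missing Markov parents — are marginalized by
    exact summation; an impossible panel is clamped to :data:`LOG_FLOOR`.
    """
    if not 0 <= c < params.n_classes:
        raise IndexError(f"class index {c} out of range for n={params.n_classes}")
    ll = loglik_matrix(y[None], mask[None], params)
    return float(ll[0, c])


def marginal_loglik(
    y: np.ndarray, mask: np.ndarray, params: ModelParams, spec: ModelSpec | None = None
) -> float:
    """log sum_c pi_c P(panel | c), computed via log-sum-exp."""
    ll = loglik_matrix(y[None], mask[None], params)[0]
    logw = np.log(np.clip(params.weights, 1e-300, None))
    m = np.max(logw + ll)
    return float(m + np.log(np.sum(np.exp(logw + ll - m))))


def model_implied_prevalence(params: ModelParams) -> np.ndarray:
    """Marginal P(y[s, t] = 1 | class), shape (n, S, T)."""
    if params.family == "latent_profile":
        return np.array(params.emit, dtype=float)
    n, S = params.init.shape
    T = params.trans[0].shape[1] + 1
    bits = state_bits(S).astype(float)  # (K, S)
    dist = initial_state_probs(params)  # (n, K)
    tmats = joint_transition_matrices(params)
    out = np.zeros((n, S, T))
    for t in range(T):
        if t > 0:
            dist = np.einsum("nk,nkl->nl", dist, tmats[:, t - 1])
        out[:, :, t] = dist @ bits
    return out


def sample_panels(
    params: ModelParams, n_children: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw complete panels from the mixture; returns (y (N,S,T), class labels)."""
    params.validate()
    S, T = params.shape
    labels = rng.choice(params.n_classes, size=n_children, p=params.weights)
    y = np.zeros((n_children, S, T), dtype=np.int8)
    if params.family == "latent_profile":
        u = rng.random((n_children, S, T))
        y[:] = (u < params.emit[labels]).astype(np.int8)
        return y, labels
    parents = parent_symptoms(params.family, S)
    u = rng.random((n_children, S, T))
    y[:, :, 0] = (u[:, :, 0] < params.init[labels]).astype(np.int8)
    for t in range(1, T):
        for s in range(S):
            cfg = np.zeros(n_children, dtype=np.int64)
            for j, p in enumerate(parents[s]):
                cfg += y[:, p, t - 1].astype(np.int64) << j
            prob = params.trans[s][labels, t - 1, cfg]
            y[:, s, t] = (u[:, s, t] < prob).astype(np.int8)
    return y, labels


def make_params(
    spec: ModelSpec,
    weights: np.ndarray,
    *,
    emit: np.ndarray | None = None,
    init: np.ndarray | None = None,
    trans: list[np.ndarray] | None = None,
) -> ModelParams:
    """Assemble and validate a ModelParams for the given spec."""
    params = ModelParams(spec.family, np.asarray(weights, dtype=float), emit=emit, init=init, trans=trans)
    params.validate()
    if params.n_classes != spec.n_classes:
        raise ValueError("weights length does not match spec.n_classes")
    return params


def trans_shapes(family: str, n_classes: int, n_symptoms: int, n_times: int) -> list[tuple[int, int, int]]:
    """Shapes of the per-symptom transition arrays for a Markov family."""
    return [
        (n_classes, n_times - 1, 2 ** len(p))
        for p in parent_symptoms(family, n_symptoms)
    ]
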