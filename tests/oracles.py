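"""Independent brute-force oracles used to verify likelihoods and posteriors.

These re-derive each family's factorization with explicit Python loops and
exhaustive enumeration over missing cells; they share no code with the
package's vectorized forward-pass implementation.
"""

import itertools

import numpy as np

PARENTS = {
    "independent_markov": {0: [0], 1: [1], 2: [2]},
    "atopic_march_markov": {0: [0], 1: [1, 0], 2: [2, 1]},
}


def complete_panel_prob(panel: np.ndarray, c: int, params) -> float:
    """P(complete panel | class c) by direct multiplication."""
    S, T = panel.shape
    prob = 1.0
    if params.family == "latent_profile":
        for s in range(S):
            for t in range(T):
                p = params.emit[c, s, t]
                prob *= p if panel[s, t] == 1 else 1.0 - p
        return prob
    parents = PARENTS[params.family]
    for s in range(S):
        p = params.init[c, s]
        prob *= p if panel[s, 0] == 1 else 1.0 - p
        for t in range(1, T):
            cfg = sum(int(panel[par, t - 1]) << j for j, par in enumerate(parents[s]))
            p = params.trans[s][c, t - 1, cfg]
            prob *= p if panel[s, t] == 1 else 1.0 - p
    return prob


def observed_prob(y: np.ndarray, mask: np.ndarray, c: int, params) -> float:
    """P(observed cells | class c): sum over completions of the missing cells."""
    miss = np.argwhere(~mask)
    total = 0.0
    for fill in itertools.product([0, 1], repeat=len(miss)):
        panel = y.copy()
        for (s, t), v in zip(miss, fill):
            panel[s, t] = v
        total += complete_panel_prob(panel, c, params)
    return total


def marginal_prob(y, mask, params) -> float:
    return sum(
        params.weights[c] * observed_prob(y, mask, c, params)
        for c in range(len(params.weights))
    )


def posterior(y, mask, params) -> np.ndarray:
    probs = np.array(
        [params.weights[c] * observed_prob(y, mask, c, params) for c in range(len(params.weights))]
    )
    return probs / probs.sum()


def random_params(family: str, n: int, S: int, T: int, rng: np.random.Generator):
    from trajmix.latent_models import ModelParams, trans_shapes

    weights = rng.dirichlet(np.ones(n) * 3)
    if family == "latent_profile":
        return ModelParams(family, weights, emit=rng.uniform(0.1, 0.9, (n, S, T)))
    shapes = trans_shapes(family, n, S, T)
    return ModelParams(
        family,
        weights,
        init=rng.uniform(0.1, 0.9, (n, S)),
        trans=[rng.uniform(0.1, 0.9, sh) for sh in shapes],
    )
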