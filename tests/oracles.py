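"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles and shares no code with
the package: exhaustive path enumeration for the copying model, Cohen's
kappa straight from contingency marginals, and a double-loop relationship
matrix.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def enumerate_copying_posteriors(
    obs: np.ndarray, ref: np.ndarray, switch_rate: float, emission_error: float
) -> np.ndarray:
    """State posteriors (T, K) by summing over all K**T copying paths."""
    K, T = ref.shape
    stay = (1.0 - switch_rate) + switch_rate / K
    move = switch_rate / K
    post = np.zeros((T, K))
    for path in product(range(K), repeat=T):
        pr = 1.0 / K
        for t in range(T):
            if t > 0:
                pr *= stay if path[t] == path[t - 1] else move
            a = obs[t]
            if a >= 0:
                pr *= (1.0 - emission_error) if ref[path[t], t] == a else emission_error
        for t in range(T):
            post[t, path[t]] += pr
    return post / post.sum(axis=1, keepdims=True)


def kappa_from_table(table: np.ndarray) -> float:
    """Cohen's kappa from a square contingency table (marginal formula)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    po = sum(table[i, i] for i in range(table.shape[0])) / n
    pe = sum(table[i, :].sum() * table[:, i].sum() for i in range(table.shape[0])) / n**2
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


def brute_force_grm(calls: np.ndarray) -> np.ndarray:
    """Standardized relationship matrix via explicit double loops."""
    calls = np.asarray(calls, dtype=float)
    n, m_all = calls.shape
    obs = calls >= 0
    p = np.array(
        [calls[obs[:, j], j].sum() / (2.0 * obs[:, j].sum()) for j in range(m_all)]
    )
    poly = [j for j in range(m_all) if 0.0 < p[j] < 1.0]
    G = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            acc = 0.0
            for j in poly:
                xa = calls[a, j] if obs[a, j] else 2.0 * p[j]
                xb = calls[b, j] if obs[b, j] else 2.0 * p[j]
                acc += (xa - 2 * p[j]) * (xb - 2 * p[j]) / (2 * p[j] * (1 - p[j]))
            G[a, b] = acc / len(poly)
    return G


def random_contingency_table(
    rng: np.random.Generator, n: int = 30, require_variation: bool = False
) -> np.ndarray:
    """Random 3x3 truth-by-imputed table with N observations."""
    while True:
        probs = rng.dirichlet(np.ones(9))
        table = rng.multinomial(n, probs).reshape(3, 3)
        if not require_variation:
            return table
        rows = (table.sum(axis=1) > 0).sum()
        cols = (table.sum(axis=0) > 0).sum()
        if rows >= 2 and cols >= 2:
            return table
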