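"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive every quantity from first
principles (exhaustive path enumeration, explicit set-partition sweeps,
textbook formulas) so they share no code path with the package.
"""

import itertools

import numpy as np
import pytest

from neurowalk.connectivity import ConnectivityMatrix
from neurowalk.core import Recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_channel_rec(rng):
    return Recording(["C3", "C4"], 100.0, rng.normal(0.0, 20.0, (2, 200)))


def random_weighted_conn(n: int, rng, density: float = 0.7,
                         max_w: float = 1.0) -> ConnectivityMatrix:
    """Random symmetric nonnegative matrix with zero diagonal."""
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < density
    W[iu[mask], ju[mask]] = rng.uniform(0.05, max_w, mask.sum())
    W = W + W.T
    labels = [f"N{i}" for i in range(n)]
    return ConnectivityMatrix(labels, W, method="pearson")


# ---------------------------------------------------------------------------
# oracles


def brute_force_shortest_path(D: np.ndarray, i: int, j: int) -> float:
    """Minimum path cost from i to j by exhaustive DFS over simple paths."""
    n = D.shape[0]
    best = [np.inf]

    def visit(node, cost, seen):
        if cost >= best[0]:
            return
        if node == j:
            best[0] = cost
            return
        for nxt in range(n):
            if nxt not in seen and np.isfinite(D[node, nxt]) and D[node, nxt] > 0:
                visit(nxt, cost + D[node, nxt], seen | {nxt})

    visit(i, 0.0, {i})
    return best[0]


def brute_force_efficiency(D: np.ndarray) -> float:
    """Mean inverse shortest-path length via the DFS oracle."""
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = brute_force_shortest_path(D, i, j)
            total += 0.0 if np.isinf(d) else 1.0 / d
    return total / (n * (n - 1))


def modularity_oracle(W: np.ndarray, communities) -> float:
    """Newman Q from the pairwise definition:
    Q = (1/2m) * sum_ij (W_ij - k_i k_j / 2m) * delta(c_i, c_j)."""
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    k = W.sum(axis=1)
    n = W.shape[0]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if communities[i] == communities[j]:
                q += W[i, j] - k[i] * k[j] / two_m
    return q / two_m


def all_partitions(items):
    """Every set partition of items (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in all_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield [[first]] + part


def max_modularity_exhaustive(W: np.ndarray) -> float:
    """Maximum Q over all set partitions of the nodes (feasible to ~8)."""
    n = W.shape[0]
    best = -np.inf
    for part in all_partitions(range(n)):
        comm = np.empty(n, dtype=int)
        for ci, group in enumerate(part):
            comm[group] = ci
        best = max(best, modularity_oracle(W, comm))
    return best


def pearson_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / (sigma_x sigma_y) with explicit loops avoided
    only for numerical parity."""
    mx, my = x.mean(), y.mean()
    num = ((x - mx) * (y - my)).sum()
    den = np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())
    return num / den


def midrank_oracle(v: np.ndarray) -> np.ndarray:
    """Average ranks with explicit tie handling."""
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(len(v))
    i = 0
    sv = v[order]
    while i < len(v):
        j = i
        while j + 1 < len(v) and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks
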