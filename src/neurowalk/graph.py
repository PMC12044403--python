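"""Graph-theoretic network measures.

* **network_efficiency** — the mean of inverse shortest-path lengths over
  all node pairs (Dijkstra on the distance matrix), optionally restricted
  to the subgraph induced by a region's electrodes. With all edge weights
  <= 1 the measure lies in [0, 1]: 1 for a fully connected unit-weight
  graph, 0 for a totally disconnected one. (Some of the EEG literature
  calls this quantity "local efficiency" when applied to brain networks;
  it is the canonical *global* efficiency formula.)
* **louvain_partition / modularity_q** — Louvain community detection and
  Newman's modularity Q under the configuration null model.
* **eigenvector_centrality** — leading eigenvector of the adjacency matrix
  by power iteration, unit Euclidean norm, nonnegative orientation.
* **regional_value** — regional aggregation of either measure over the
  electrode-region parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityMatrix, DistanceMatrix
from .core import RegionMap

__all__ = [
    "GraphPartition",
    "CentralityVector",
    "network_efficiency",
    "louvain_partition",
    "modularity_q",
    "eigenvector_centrality",
    "regional_value",
]


@dataclass
class GraphPartition:
    """A node partition with its modularity score."""

    labels: list[str]
    communities: list[int]   # community id per node, aligned with labels
    Q: float

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.labels, self.communities))


@dataclass
class CentralityVector:
    """Per-node nonnegative centrality, unit Euclidean norm."""

    labels: list[str]
    c: np.ndarray

    def __getitem__(self, label: str) -> float:
        low = label.lower()
        for i, l in enumerate(self.labels):
            if l.lower() == low:
                return float(self.c[i])
        raise KeyError(label)


def _subset_indices(labels: list[str], subset) -> list[int]:
    lowered = {l.lower(): i for i, l in enumerate(labels)}
    idx = []
    missing = []
    for lab in subset:
        i = lowered.get(lab.lower())
        if i is None:
            missing.append(lab)
        else:
            idx.append(i)
    if missing:
        raise KeyError(f"labels not in matrix: {missing}")
    return idx


def network_efficiency(dist: DistanceMatrix, subset=None) -> float:
    """Mean inverse shortest-path length over all ordered node pairs.

    ``E = (1 / (m (m-1))) * sum_{i != j} 1 / d_ij`` with ``d_ij`` the
    shortest-path distance; disconnected pairs contribute 0. If ``subset``
    is given, paths are confined to the induced subgraph.
    """
    D = dist.D
    if subset is not None:
        idx = _subset_indices(dist.labels, subset)
        if len(idx) < 2:
            raise ValueError("subset must contain at least 2 labels")
        D = D[np.ix_(idx, idx)]
    m = D.shape[0]
    finite = np.isfinite(D) & (D > 0)
    rows, cols = np.nonzero(np.triu(finite, k=1))
    graph = sp.csr_matrix((D[rows, cols], (rows, cols)), shape=(m, m))
    sp_dist = dijkstra(graph, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / sp_dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (m * (m - 1)))


def modularity_q(adj: ConnectivityMatrix, partition) -> float:
    """Newman modularity of a partition of an undirected weighted graph.

    ``Q = sum_c [ e_c / m - (k_c / (2 m))^2 ]`` with ``e_c`` the total
    within-community edge weight, ``k_c`` the community degree sum and
    ``m`` the total edge weight. An empty graph has Q = 0 by convention.
    """
    W = adj.W
    labels = adj.labels
    if isinstance(partition, GraphPartition):
        comm_of = partition.as_dict()
    elif isinstance(partition, dict):
        comm_of = partition
    else:  # iterable of communities (sets of labels)
        comm_of = {lab: ci for ci, group in enumerate(partition)
                   for lab in group}
    missing = [l for l in labels if l not in comm_of]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing}")
    cid = np.array([comm_of[l] for l in labels])
    two_m = W.sum()
    if two_m == 0:
        return 0.0
    degrees = W.sum(axis=1)
    q = 0.0
    for c in np.unique(cid):
        members = cid == c
        e_c = W[np.ix_(members, members)].sum() / 2.0   # within weight
        k_c = degrees[members].sum()
        q += e_c / (two_m / 2.0) - (k_c / two_m) ** 2
    return float(q)


def louvain_partition(adj: ConnectivityMatrix, seed: int = 0,
                      n_restarts: int = 8) -> GraphPartition:
    """Louvain community detection (greedy local moving + aggregation).

    The greedy sweep is sensitive to node order, so the algorithm is run
    ``n_restarts`` times with sweep orders derived deterministically from
    ``seed`` and the partition with the highest modularity is returned
    (a standard remedy for Louvain's order dependence). Q is computed by
    :func:`modularity_q` on the winning partition. A graph with no edges
    yields one community per node and Q = 0.
    """
    import random

    import igraph as ig

    W = adj.W
    if np.any(W < 0):
        raise ValueError("louvain_partition requires nonnegative weights")
    n = adj.n
    iu, ju = np.nonzero(np.triu(W, k=1))
    if len(iu) == 0:
        return GraphPartition(list(adj.labels), list(range(n)), 0.0)
    G = ig.Graph(n=n, edges=list(zip(iu.tolist(), ju.tolist())))
    weights = W[iu, ju].tolist()
    best: GraphPartition | None = None
    try:
        for r in range(max(1, n_restarts)):
            ig.set_random_number_generator(
                random.Random(int(seed) + 7919 * r))
            clustering = G.community_multilevel(weights=weights)
            part = GraphPartition(list(adj.labels),
                                  list(clustering.membership), 0.0)
            part.Q = modularity_q(adj, part)
            if best is None or part.Q > best.Q:
                best = part
    finally:
        ig.set_random_number_generator(random)  # restore module default
    return best


def eigenvector_centrality(adj: ConnectivityMatrix, tol: float = 1e-10,
                           max_iter: int = 1000) -> CentralityVector:
    """Leading eigenvector of the adjacency matrix by power iteration.

    The iteration runs on A + I (same eigenvectors, spectrum shifted
    positive) with renormalization each step, and stops when successive
    iterates agree to ``tol`` in max-norm. The result is oriented
    nonnegative and scaled to unit Euclidean norm. On a disconnected graph
    the mass concentrates on the component with the largest eigenvalue.
    """
    A = adj.W
    if np.any(A < 0):
        raise ValueError("eigenvector centrality requires nonnegative weights")
    if not np.any(A > 0):
        raise ValueError("graph has no edges")
    n = adj.n
    x = np.full(n, 1.0 / np.sqrt(n))
    for iteration in range(1, max_iter + 1):
        y = A @ x + x
        y_norm = np.linalg.norm(y)
        if y_norm == 0:
            raise RuntimeError("power iteration collapsed to zero vector")
        y /= y_norm
        if np.abs(y - x).max() < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations")
    if x.sum() < 0:
        x = -x
    x = np.clip(x, 0.0, None)
    x /= np.linalg.norm(x)
    return CentralityVector(list(adj.labels), x)


def regional_value(value, region: str, region_map: RegionMap,
                   mode: str) -> float:
    """Regional aggregate of a network measure.

    ``mode="efficiency"`` — efficiency of the region-induced subgraph
    (``value`` must be a DistanceMatrix; paths may not leave the region).
    ``mode="centrality"`` — mean eigenvector centrality over the region's
    electrodes (``value`` must be a CentralityVector).
    """
    if region not in region_map:
        raise KeyError(f"unknown region {region!r}")
    electrodes = region_map.electrodes(region)
    if mode == "efficiency":
        if not isinstance(value, DistanceMatrix):
            raise TypeError("efficiency mode needs a DistanceMatrix")
        return network_efficiency(value, subset=electrodes)
    if mode == "centrality":
        if not isinstance(value, CentralityVector):
            raise TypeError("centrality mode needs a CentralityVector")
        lowered = {l.lower(): i for i, l in enumerate(value.labels)}
        missing = [e for e in electrodes if e.lower() not in lowered]
        if missing:
            raise KeyError(f"region electrodes absent from data: {missing}")
        idx = [lowered[e.lower()] for e in electrodes]
        return float(value.c[idx].mean())
    raise ValueError(f"unknown mode {mode!r}")
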