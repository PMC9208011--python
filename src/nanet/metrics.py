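"""Weighted network topology metrics and degree-preserving null models.

Definitions follow the standard weighted forms of the Brain Connectivity
Toolbox: Onnela geometric-mean clustering on weights rescaled by the matrix
maximum, shortest paths on lengths 1/|w|, betweenness normalized by
(N-1)(N-2)/2, and global efficiency as the mean inverse distance over ordered
pairs. Signed functional weights enter all metrics through their absolute
value (nonnegativity is required by the weighted definitions); the fraction
of negative edges is available via :func:`negative_edge_fraction`.
"""

from __future__ import annotations

from typing import Callable

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .types import as_seedseq


def _as_weight_matrix(A: np.ndarray) -> np.ndarray:
    W = np.abs(np.asarray(A, dtype=float))
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(W, W.T):
        raise ValueError("adjacency must be symmetric")
    W = W.copy()
    np.fill_diagonal(W, 0.0)
    return W


def negative_edge_fraction(A: np.ndarray) -> float:
    A = np.asarray(A, dtype=float)
    nz = np.count_nonzero(np.triu(A, 1))
    return float(np.count_nonzero(np.triu(A, 1) < 0) / nz) if nz else 0.0


def density(A: np.ndarray) -> float:
    """Fraction of realized unordered edges, kappa."""
    W = _as_weight_matrix(A)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    return float(np.count_nonzero(np.triu(W, 1)) / (n * (n - 1) / 2))


def normalized_degree(A: np.ndarray) -> float:
    """Mean degree divided by (N - 1)."""
    W = _as_weight_matrix(A)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    return float((W > 0).sum(axis=1).mean() / (n - 1))


def mean_normalized_strength(A: np.ndarray) -> float:
    """Mean over nodes of total absolute weight divided by (N - 1), S."""
    W = _as_weight_matrix(A)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    return float((W.sum(axis=1) / (n - 1)).mean())


def onnela_clustering(A: np.ndarray) -> np.ndarray:
    """Per-node Onnela weighted clustering; nodes of degree < 2 get 0."""
    W = _as_weight_matrix(A)
    mx = W.max()
    if mx == 0:
        return np.zeros(W.shape[0])
    What = np.cbrt(W / mx)
    cyc = np.diagonal(What @ What @ What)
    k = (W > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, cyc / denom, 0.0)
    return C


def clustering_coefficient(A: np.ndarray) -> float:
    """Mean Onnela clustering over all nodes (degree < 2 contributes 0)."""
    return float(onnela_clustering(A).mean())


def _length_graph(W: np.ndarray) -> csr_array:
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / W, 0.0)
    return csr_array(L)


def shortest_path_lengths(A: np.ndarray) -> np.ndarray:
    """All-pairs weighted distances on lengths 1/|w| (inf if disconnected)."""
    W = _as_weight_matrix(A)
    return dijkstra(_length_graph(W), directed=False)


def global_efficiency(A: np.ndarray) -> float:
    """Mean inverse shortest-path distance over ordered node pairs, E."""
    W = _as_weight_matrix(A)
    n = W.shape[0]
    if n < 2:
        raise ValueError("need >= 2 nodes")
    D = dijkstra(_length_graph(W), directed=False)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / D, 0.0)
    return float(inv[off].mean())


def betweenness_per_node(A: np.ndarray) -> np.ndarray:
    """Weighted betweenness on lengths 1/|w|, normalized by (N-1)(N-2)/2."""
    W = _as_weight_matrix(A)
    n = W.shape[0]
    if n < 3:
        return np.zeros(n)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    ii, jj = np.nonzero(np.triu(W, 1))
    G.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / W[i, j]) for i, j in zip(ii, jj)), weight="length"
    )
    bc = nx.betweenness_centrality(G, normalized=True, weight="length")
    return np.array([bc[i] for i in range(n)])


def normalized_betweenness(A: np.ndarray) -> float:
    """Mean normalized weighted betweenness over nodes, B."""
    return float(betweenness_per_node(A).mean())


#: Metric registry; keys match the tidy-table metric names.
METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "kappa": density,
    "K": normalized_degree,
    "S": mean_normalized_strength,
    "C": clustering_coefficient,
    "B": normalized_betweenness,
    "E": global_efficiency,
}


def degree_preserving_rewire(
    A: np.ndarray, seed=0, iterations: int = 100
) -> np.ndarray:
    """Maslov-Sneppen edge-swap randomization carrying weights on edges.

    Attempts ``iterations`` swap proposals per edge, each exchanging the
    endpoints of two randomly chosen edges when the swap keeps the graph
    simple. The degree sequence and edge count are preserved exactly; edge
    weights travel with their (rewired) edges. Networks with three or fewer
    edges are returned unchanged.
    """
    Asym = np.asarray(A, dtype=float)
    W = _as_weight_matrix(Asym)  # shape/symmetry validation
    n = W.shape[0]
    ii, jj = np.nonzero(np.triu(W, 1))
    K = len(ii)
    if K <= 3:
        return Asym.copy()
    e1 = [int(v) for v in ii]
    e2 = [int(v) for v in jj]
    wts = np.array([Asym[i, j] for i, j in zip(ii, jj)])
    edge_set = set(zip(e1, e2))

    rng = np.random.default_rng(seed)
    n_attempts = K * iterations
    ea = rng.integers(0, K, size=n_attempts).tolist()
    eb = rng.integers(0, K, size=n_attempts).tolist()
    flips = (rng.uniform(size=n_attempts) < 0.5).tolist()
    for a, b, flip in zip(ea, eb, flips):
        if a == b:
            continue
        i, j = e1[a], e2[a]
        k, l = e1[b], e2[b]
        if flip:
            k, l = l, k
        if i == k or i == l or j == k or j == l:
            continue
        new1 = (i, l) if i < l else (l, i)
        new2 = (k, j) if k < j else (j, k)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.remove((e1[a], e2[a]))
        edge_set.remove((e1[b], e2[b]))
        edge_set.add(new1)
        edge_set.add(new2)
        e1[a], e2[a] = new1
        e1[b], e2[b] = new2
    out = np.zeros_like(W)
    out[e1, e2] = wts  # signed weights travel with their edges
    out[e2, e1] = wts
    return out


def metric_vs_null(
    A: np.ndarray,
    metric: str | Callable[[np.ndarray], float],
    n_null: int = 100,
    seed=0,
    iterations: int = 100,
) -> tuple[float, float, float, np.ndarray]:
    """Observed metric, rewired-null ensemble mean, and their difference.

    Returns ``(observed, null_mean, delta, null_values)`` with
    ``delta = observed - null_mean``. Per-dish deltas feed the one-sample
    t tests of the statistical pipeline.
    """
    if n_null < 10:
        raise ValueError("need at least 10 null networks")
    fn = METRICS[metric] if isinstance(metric, str) else metric
    observed = fn(A)
    seeds = as_seedseq(seed).spawn(n_null)
    null_values = np.array(
        [fn(degree_preserving_rewire(A, seed=s, iterations=iterations)) for s in seeds]
    )
    null_mean = float(null_values.mean())
    return float(observed), null_mean, float(observed - null_mean), null_values


def metrics_vs_null_ensemble(
    A: np.ndarray,
    metrics: tuple[str, ...] = ("C", "B", "E"),
    n_null: int = 100,
    seed=0,
    iterations: int = 100,
) -> dict[str, tuple[float, float, float]]:
    """Evaluate several metrics against one shared rewired-null ensemble.

    Returns ``{metric: (observed, null_mean, delta)}``; amortizes the
    rewiring cost across metrics.
    """
    if n_null < 10:
        raise ValueError("need at least 10 null networks")
    seeds = as_seedseq(seed).spawn(n_null)
    nulls = [degree_preserving_rewire(A, seed=s, iterations=iterations) for s in seeds]
    out: dict[str, tuple[float, float, float]] = {}
    for m in metrics:
        fn = METRICS[m]
        obs = float(fn(A))
        null_mean = float(np.mean([fn(R) for R in nulls]))
        out[m] = (obs, null_mean, obs - null_mean)
    return out
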