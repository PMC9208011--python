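"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths (scipy.csgraph / networkx):
distances come from a hand-rolled Floyd-Warshall, and betweenness from
exhaustive enumeration of all simple paths on tiny graphs.
"""

from itertools import permutations

import numpy as np


def floyd_warshall_distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances on lengths 1/|w|, by triple loop."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / abs(W[i, j])
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    return D


def brute_global_efficiency(W: np.ndarray) -> float:
    D = floyd_warshall_distances(np.abs(W))
    n = W.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(D[i, j]) and D[i, j] > 0:
                total += 1.0 / D[i, j]
    return total / (n * (n - 1))


def brute_betweenness(W: np.ndarray) -> np.ndarray:
    """Normalized betweenness by enumerating every simple path (n <= 7)."""
    W = np.abs(W)
    n = W.shape[0]
    best_len = np.full((n, n), np.inf)
    paths_by_pair: dict[tuple[int, int], list[tuple[int, ...]]] = {}
    nodes = list(range(n))
    for s in range(n):
        for t in range(s + 1, n):
            paths = []
            inner = [v for v in nodes if v not in (s, t)]
            for r in range(len(inner) + 1):
                for mid in permutations(inner, r):
                    path = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(path, path[1:]):
                        if W[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / W[a, b]
                    if ok:
                        paths.append((length, path))
            if paths:
                lmin = min(p[0] for p in paths)
                best_len[s, t] = lmin
                paths_by_pair[(s, t)] = [
                    p for ln, p in paths if np.isclose(ln, lmin)
                ]
    bc = np.zeros(n)
    for (s, t), plist in paths_by_pair.items():
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in plist if v in p)
            bc[v] += through / len(plist)
    norm = (n - 1) * (n - 2) / 2
    return bc / norm if norm > 0 else bc


def random_symmetric_graph(n: int, density: float, rng) -> np.ndarray:
    """Random weighted undirected graph with weights in (0.1, 1]."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.uniform() < density:
                W[i, j] = W[j, i] = rng.uniform(0.1, 1.0)
    return W
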