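"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately naive — exhaustive triple counting,
Floyd-Warshall distances, explicit geodesic enumeration — and shares no
code with the package's graph module, so agreement is a genuine
cross-check.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj > 0] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_per_node(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if adj[v, u]]
        k = len(nb)
        if k < 2:
            continue
        triangles = sum(
            1 for a, b in itertools.combinations(nb, 2) if adj[a, b]
        )
        out[v] = 2.0 * triangles / (k * (k - 1))
    return out


def harmonic_path_length(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    if total == 0.0:
        raise ValueError("no connected pair")
    return n * (n - 1) / total


def global_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    total = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and np.isfinite(d[i, j])
    )
    return total / (n * (n - 1))


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])
        ) / (n - 1)
    return out


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = np.zeros(n)
    for v in range(n):
        nb = [u for u in range(n) if adj[v, u]]
        if len(nb) >= 2:
            sub = adj[np.ix_(nb, nb)]
            vals[v] = global_efficiency(sub)
    return float(vals.mean())


def _all_geodesics(adj: np.ndarray, s: int, t: int, d: np.ndarray):
    """Enumerate every shortest s-t path by depth-first extension."""
    if not np.isfinite(d[s, t]):
        return []
    paths = []
    stack = [(s, [s])]
    while stack:
        node, path = stack.pop()
        if node == t:
            paths.append(path)
            continue
        for u in range(adj.shape[0]):
            if adj[node, u] and d[s, u] == len(path) and d[u, t] == d[s, t] - len(path):
                stack.append((u, path + [u]))
    return paths


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness, each unordered pair counted once."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    out = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = _all_geodesics(adj, s, t, d)
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    out[v] += 1.0 / len(paths)
    return out


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Direct covariance/variance arithmetic, no numpy.corrcoef."""
    xm = x - sum(x) / len(x)
    ym = y - sum(y) / len(y)
    return float(sum(xm * ym) / (sum(xm * xm) ** 0.5 * sum(ym * ym) ** 0.5))


def random_adjacency(rng: np.random.Generator, n: int, p: float = 0.35) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, k=1)
    a = a + a.T
    if a.sum() == 0:  # guarantee at least one edge
        a[0, 1] = a[1, 0] = 1
    return a
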