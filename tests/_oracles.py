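"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: distances come from
a textbook Floyd-Warshall triple loop, and the LSSVR oracle solves the KKT
conditions by block elimination instead of assembling the saddle system.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """Textbook O(n^3) all-pairs shortest paths on a 0/1 adjacency matrix."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and adj[i, j]:
                d[i, j] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency_oracle(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    if n < 2:
        return 0.0
    vals = [1.0 / d[i, j] if np.isfinite(d[i, j]) else 0.0
            for i in range(n) for j in range(n) if i != j]
    return float(np.mean(vals))


def local_efficiency_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        total += global_efficiency_oracle(sub)
    return total / n


def path_length_oracle(adj: np.ndarray) -> float:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def node_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    d = floyd_warshall(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(1.0 / d[i, j] for j in range(n)
                     if j != i and np.isfinite(d[i, j])) / (n - 1)
    return out


def clustering_oracle(adj: np.ndarray) -> float:
    n = adj.shape[0]
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(adj[a, b] for ai, a in enumerate(nbrs)
                    for b in nbrs[ai + 1:])
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def random_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    a = (rng.random((n, n)) < density).astype(np.int8)
    a = np.triu(a, 1)
    return a + a.T


def lssvr_block_oracle(K: np.ndarray, y: np.ndarray, J: float):
    """KKT solution by block elimination: M = K + I/J,
    b = (1^T M^-1 y) / (1^T M^-1 1), a = M^-1 (y - b 1)."""
    n = len(y)
    M = K + np.eye(n) / J
    Minv = np.linalg.inv(M)
    one = np.ones(n)
    b = (one @ Minv @ y) / (one @ Minv @ one)
    a = Minv @ (y - b * one)
    return b, a
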