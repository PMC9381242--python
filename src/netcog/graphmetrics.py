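"""Global and nodal topology of binarized brain networks.

Seven global metrics are tracked across the sparsity grid: global efficiency
(Eglobal), local efficiency (Elocal), mean clustering coefficient (Cp),
characteristic path length (Lp), and the small-world triplet gamma, lambda,
sigma in which Cp and Lp are normalized by degree-preserving random null
networks (gamma = Cp/<Cp_null>, lambda = Lp/<Lp_null>, sigma = gamma/lambda).
Each metric's curve over the grid is summarized by its trapezoidal area under
the curve (AUC), giving one scalar feature per metric per subject that
reflects topology across the whole threshold range rather than at any single
arbitrary sparsity.

Distances are unweighted shortest-path lengths (scipy.sparse.csgraph);
disconnected pairs have infinite distance, which the efficiency metrics
absorb naturally as 1/inf = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .connectome import BinaryGraph, ZMatrix, _ranked_edges, binarize_at_sparsity

__all__ = [
    "METRIC_NAMES",
    "NullConfig",
    "NullEnsemble",
    "MetricCurveSet",
    "clustering_coefficient",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "node_efficiency",
    "rewire_null",
    "build_null_ensemble",
    "normalized_smallworld",
    "metric_curves",
    "auc",
]

#: canonical feature order used throughout the package
METRIC_NAMES = ("gamma", "lambda", "sigma", "cp", "lp", "eglobal", "elocal")


@dataclass
class NullConfig:
    """Degree-preserving null-model settings for the normalized metrics."""

    n_nulls: int = 100
    n_rewires_per_edge: int = 10
    seed: int = 0


@dataclass
class NullEnsemble:
    """Degree-matched random graphs for one source graph."""

    graphs: list[BinaryGraph]
    n_rewires_per_edge: int
    seed: int


@dataclass
class MetricCurveSet:
    """Per-metric curves over the sparsity grid plus their AUCs."""

    grid: np.ndarray
    curves: dict[str, np.ndarray]
    aucs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aucs:
            self.aucs = {k: auc(v, self.grid) for k, v in self.curves.items()}


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths by level-wise BFS.

    Expands reachability with boolean matrix products, recording the level
    at which each pair is first reached; unreachable pairs stay at inf.
    Runs in O(diameter * n^3) bit operations, which beats per-source
    Dijkstra for the dense small graphs used here.
    """
    a = np.asarray(adj, dtype=bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[a] = 1.0
    reach = a | np.eye(n, dtype=bool)
    level = 1
    while True:
        grown = (reach.astype(np.uint8) @ a.astype(np.uint8)) > 0
        grown |= reach
        new = grown & ~reach
        if not new.any():
            break
        level += 1
        dist[new] = level
        reach = grown
    return dist


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = off & np.isfinite(d)
    inv[finite] = 1.0 / d[finite]
    return float(inv[off].mean())


def clustering_coefficient(g: BinaryGraph) -> float:
    """Mean local clustering: fraction of closed triples around each node.

    Nodes with degree < 2 contribute 0 (they close no triple).
    """
    a = np.asarray(g.adjacency, dtype=float)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return float(c.mean())


def characteristic_path_length(g: BinaryGraph) -> float:
    """Mean shortest-path length over reachable node pairs.

    Unreachable pairs are excluded with a warning; if no pair is reachable
    the value is undefined and NaN is returned (with a warning).
    """
    d = _distances(g.adjacency)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if finite.sum() < off.sum():
        warnings.warn(
            "graph is disconnected; characteristic path length computed over "
            "reachable pairs only",
            stacklevel=2,
        )
    if not finite.any():
        return float("nan")
    return float(d[finite].mean())


def global_efficiency(g: BinaryGraph) -> float:
    """Mean inverse shortest-path length over node pairs (1/inf = 0)."""
    return _efficiency_from_distances(_distances(g.adjacency))


def local_efficiency(g: BinaryGraph) -> float:
    """Mean over nodes of the global efficiency of each neighbor subgraph.

    Nodes with fewer than two neighbors contribute 0.
    """
    a = np.asarray(g.adjacency)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        total += _efficiency_from_distances(_distances(sub))
    return total / n


def node_efficiency(g: BinaryGraph) -> np.ndarray:
    """Per-node efficiency E_i = mean_j 1/d_ij, a node-centrality measure."""
    d = _distances(g.adjacency)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    inv = np.zeros_like(d)
    finite = off & np.isfinite(d)
    inv[finite] = 1.0 / d[finite]
    return inv.sum(axis=1) / (n - 1)


def rewire_null(
    g: BinaryGraph, n_rewires_per_edge: int, rng: np.random.Generator
) -> BinaryGraph:
    """Degree-preserving randomization by Maslov-Sneppen double-edge swaps.

    Each attempt picks two edges (a,b), (c,d) and rewires them to (a,d),
    (c,b) when that creates no self-loop or duplicate edge; the number of
    attempts is ``n_rewires_per_edge * n_edges``. Degree sequence is
    invariant by construction. A graph with fewer than two edges is returned
    unchanged with a warning.
    """
    adj = np.array(g.adjacency, dtype=np.int8)
    iu, ju = np.nonzero(np.triu(adj, 1))
    m = iu.size
    if m < 2:
        warnings.warn("too few edges for double-edge swaps; graph unchanged",
                      stacklevel=2)
        return BinaryGraph(adjacency=adj, sparsity=g.sparsity)
    edges = np.stack([iu, ju], axis=1)
    n_attempts = n_rewires_per_edge * m
    pick = rng.integers(0, m, size=(n_attempts, 2))
    flip = rng.random(n_attempts) < 0.5
    for t in range(n_attempts):
        e1, e2 = pick[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip[t]:
            c, d = d, c
        # proposed replacement edges: (a, d) and (c, b)
        if a == d or c == b:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = adj[b, a] = 0
        adj[c, d] = adj[d, c] = 0
        adj[a, d] = adj[d, a] = 1
        adj[c, b] = adj[b, c] = 1
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    return BinaryGraph(adjacency=adj, sparsity=g.sparsity)


def build_null_ensemble(
    g: BinaryGraph, config: NullConfig, rng: np.random.Generator | None = None
) -> NullEnsemble:
    """Generate ``config.n_nulls`` degree-matched random graphs."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    graphs = [rewire_null(g, config.n_rewires_per_edge, rng)
              for _ in range(config.n_nulls)]
    return NullEnsemble(graphs=graphs,
                        n_rewires_per_edge=config.n_rewires_per_edge,
                        seed=config.seed)


def normalized_smallworld(
    g: BinaryGraph, nulls: NullEnsemble
) -> tuple[float, float, float]:
    """Small-world triplet (gamma, lambda, sigma) against a null ensemble."""
    if not nulls.graphs:
        raise ValueError("null ensemble is empty")
    cp_null = float(np.mean([clustering_coefficient(h) for h in nulls.graphs]))
    lp_null = float(np.mean([characteristic_path_length(h) for h in nulls.graphs]))
    if cp_null == 0 or lp_null == 0:
        raise ValueError("null-ensemble mean metric is zero; cannot normalize")
    gamma = clustering_coefficient(g) / cp_null
    lam = characteristic_path_length(g) / lp_null
    return gamma, lam, gamma / lam


def metric_curves(
    zm: ZMatrix,
    grid: np.ndarray,
    null_config: NullConfig | None = None,
    metrics: tuple[str, ...] = METRIC_NAMES,
) -> MetricCurveSet:
    """Evaluate the requested global metrics at every sparsity on the grid.

    The normalized metrics (gamma, lambda, sigma) require a ``null_config``;
    one independent, seeded null ensemble is built per sparsity threshold.
    Restricting ``metrics`` (e.g. to ``("elocal",)``) skips the unneeded —
    and much more expensive — null-model work.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly increasing")
    if not ((grid > 0) & (grid <= 1)).all():
        raise ValueError("grid values must lie in (0, 1]")
    unknown = set(metrics) - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    need_nulls = bool({"gamma", "lambda", "sigma"} & set(metrics))
    if need_nulls and null_config is None:
        raise ValueError("normalized metrics requested but no null_config given")

    curves: dict[str, list[float]] = {m: [] for m in metrics}
    # rank edges once per subject; each threshold keeps a prefix of the
    # ranking (identical to binarize_at_sparsity at every grid point)
    iu, ju = _ranked_edges(zm.z, rank_by_abs=False)
    n = zm.n_rois
    for k, s in enumerate(grid):
        n_edges = int(round(s * n * (n - 1) / 2))
        adj = np.zeros((n, n), dtype=np.int8)
        adj[iu[:n_edges], ju[:n_edges]] = 1
        adj |= adj.T
        g = BinaryGraph(adjacency=adj, sparsity=float(s))
        if "cp" in metrics:
            curves["cp"].append(clustering_coefficient(g))
        if "lp" in metrics:
            curves["lp"].append(characteristic_path_length(g))
        if "eglobal" in metrics:
            curves["eglobal"].append(global_efficiency(g))
        if "elocal" in metrics:
            curves["elocal"].append(local_efficiency(g))
        if need_nulls:
            rng = np.random.default_rng(
                np.random.SeedSequence([null_config.seed, k]))
            nulls = build_null_ensemble(g, null_config, rng)
            gamma, lam, sigma = normalized_smallworld(g, nulls)
            if "gamma" in metrics:
                curves["gamma"].append(gamma)
            if "lambda" in metrics:
                curves["lambda"].append(lam)
            if "sigma" in metrics:
                curves["sigma"].append(sigma)
    arr = {m: np.asarray(v, dtype=float) for m, v in curves.items()}
    return MetricCurveSet(grid=grid, curves=arr)


def auc(curve: np.ndarray, grid: np.ndarray) -> float:
    """Trapezoidal area under a metric curve over the sparsity grid."""
    curve = np.asarray(curve, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if curve.shape != grid.shape:
        raise ValueError("curve and grid lengths differ")
    if grid.size < 2:
        raise ValueError("AUC needs at least two grid points")
    if not (np.diff(grid) > 0).all():
        raise ValueError("grid must be strictly increasing")
    return float(np.trapezoid(curve, grid))
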