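"""Subject-level functional connectivity construction.

A subject's preprocessed BOLD signal is an ROI x timepoint matrix. The
connectome is built in three steps: Pearson correlation between every pair
of regional time series (a symmetric matrix with unit diagonal), a Fisher-Z
variance-stabilizing transform of the off-diagonal correlations, and
binarization of the Z matrix at a *matrix sparsity* threshold -- the
proportion of strongest connections retained as edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeriesMatrix",
    "ConnMatrix",
    "ZMatrix",
    "BinaryGraph",
    "correlation_matrix",
    "fisher_z",
    "binarize_at_sparsity",
    "sparsity_grid",
    "read_timeseries",
    "write_matrix",
    "write_edge_list",
]

#: clip bound applied to |p| = 1 correlations before the Fisher-Z transform
_CLIP = 1.0 - 1e-7


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI x timepoint signal block."""

    values: np.ndarray
    roi_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D ROI x timepoint matrix")
        if not np.isfinite(self.values).all():
            raise ValueError("time series contains missing or non-finite values")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnMatrix:
    """Pearson correlation matrix p_ij between regional time series."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)


@dataclass
class ZMatrix:
    """Fisher-Z transformed connectivity.

    The diagonal is stored as 1 to mirror the correlation matrix's unit
    diagonal, but it is a notational placeholder: binarization and every
    downstream graph metric ignore the diagonal.
    """

    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)

    @property
    def n_rois(self) -> int:
        return self.z.shape[0]


@dataclass
class BinaryGraph:
    """Undirected simple graph as a 0/1 adjacency matrix."""

    adjacency: np.ndarray
    sparsity: float = field(default=np.nan)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.triu(self.adjacency, 1).sum())


def correlation_matrix(ts: TimeSeriesMatrix) -> ConnMatrix:
    """Pearson correlation between every pair of ROI time series.

    Raises ``ValueError`` naming the offending ROI index if any row has zero
    variance (a flat regional signal carries no connectivity information).
    """
    x = ts.values
    sd = x.std(axis=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise ValueError(
            f"ROI row(s) {dead.tolist()} have zero variance; "
            "cannot compute Pearson correlations"
        )
    p = np.corrcoef(x)
    np.fill_diagonal(p, 1.0)
    return ConnMatrix(p=np.clip(p, -1.0, 1.0))


def fisher_z(conn: ConnMatrix, clip: bool = True) -> ZMatrix:
    """Fisher-Z transform z = arctanh(p) of the off-diagonal correlations.

    Perfect off-diagonal correlations (|p| = 1, possible with duplicated
    synthetic signals) are clipped to +/-(1 - 1e-7) with a warning; with
    ``clip=False`` they raise instead.
    """
    p = conn.p.copy()
    n = p.shape[0]
    off = ~np.eye(n, dtype=bool)
    extreme = off & (np.abs(p) >= 1.0)
    if extreme.any():
        if not clip:
            raise ValueError("off-diagonal |p| = 1 is outside the Fisher-Z domain")
        warnings.warn(
            f"{int(extreme.sum())} off-diagonal |p| = 1 value(s) clipped "
            "before Fisher-Z",
            stacklevel=2,
        )
        p[extreme] = np.sign(p[extreme]) * _CLIP
    z = np.zeros_like(p)
    z[off] = np.arctanh(p[off])
    np.fill_diagonal(z, 1.0)  # placeholder; never used downstream
    return ZMatrix(z=z)


def _ranked_edges(z: np.ndarray, rank_by_abs: bool) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = np.abs(z[iu, ju]) if rank_by_abs else z[iu, ju]
    # lexsort: last key is primary; negate w for descending, (iu, ju) break ties
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order]


def binarize_at_sparsity(
    zm: ZMatrix, sparsity: float, rank_by_abs: bool = False
) -> BinaryGraph:
    """Keep the ``round(sparsity * n(n-1)/2)`` strongest edges.

    Edges are ranked by z value (most positive first) by default, the
    dominant convention for binarized functional connectomes;
    ``rank_by_abs=True`` ranks by magnitude instead. Ties are broken by
    lexicographic (i, j) order so the edge set at a lower sparsity is always
    a subset of the edge set at a higher one.
    """
    if not 0.0 < sparsity <= 1.0:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = zm.n_rois
    m = int(round(sparsity * n * (n - 1) / 2))
    iu, ju = _ranked_edges(zm.z, rank_by_abs)
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[:m], ju[:m]] = 1
    adj |= adj.T
    return BinaryGraph(adjacency=adj, sparsity=float(sparsity))


def sparsity_grid(
    low: float = 0.10, high: float = 0.40, step: float = 0.01
) -> np.ndarray:
    """Sparsity threshold grid, default 0.10..0.40 in steps of 0.01.

    Realized by integer stepping (31 exact hundredths by default) to avoid
    floating-point drift in the grid values.
    """
    scale = int(round(1 / step))
    lo, hi = int(round(low * scale)), int(round(high * scale))
    return np.arange(lo, hi + 1) / scale


def read_timeseries(path) -> TimeSeriesMatrix:
    """Read a header-free delimited (CSV/TSV/whitespace) ROI x timepoint matrix."""
    values = np.loadtxt(path, delimiter=None if _is_whitespace(path) else ",")
    return TimeSeriesMatrix(values=values)


def _is_whitespace(path) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return "," not in first


def write_matrix(matrix: np.ndarray, path) -> None:
    """Write a numeric matrix as header-free CSV."""
    np.savetxt(path, np.asarray(matrix, dtype=float), delimiter=",", fmt="%.10g")


def write_edge_list(graph: BinaryGraph, path) -> None:
    """Write a BinaryGraph as ``i,j`` lines (0-based node indices)."""
    iu, ju = np.nonzero(np.triu(graph.adjacency, 1))
    with open(path, "w") as fh:
        for i, j in zip(iu, ju):
            fh.write(f"{i},{j}\n")
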