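"""Voxelwise graph metrics on thresholded connectivity graphs.

The thresholded correlation matrix is an unweighted, undirected simple
graph whose vertices are in-mask voxels.  This module loads edge lists,
computes per-vertex metrics — degree, connected-component label, triangle
count, local clustering coefficient ``tc / (d(d-1)/2)``, and PageRank — and
the edge-density statistic

    S = log E / log K,      K = 2E / N,

used to pick comparable correlation thresholds across heterogeneous
datasets (E edges, N vertices, K average degree; S is invariant to the
logarithm base).

Conventions: component labels are the minimum vertex id in each component;
local clustering is defined as 0 for degree < 2 (the formula divides by
zero there); PageRank is normalized to sum to 1 (the probability
convention), with each undirected edge treated as two directed edges and
dangling (isolated) vertices distributing their mass uniformly.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.sparse import csgraph

from .connectivity import StandardizedTable, TilePlan, WeightedEdgeList, correlation_tile
from .errors import (
    ConvergenceError,
    EdgeListParseError,
    StatisticUndefinedError,
    ThresholdRangeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SparseGraph",
    "VertexMetrics",
    "GraphSummary",
    "load_edge_list",
    "from_weighted_edges",
    "degrees",
    "connected_components",
    "triangle_counts",
    "local_clustering",
    "pagerank",
    "edge_density_statistic",
    "select_threshold",
    "compute_vertex_metrics",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SparseGraph:
    """Undirected simple graph: ``edges`` is an (E, 2) array with i < j rows.

    Isolated vertices are allowed — every id in ``[0, n_vertices)`` is a
    vertex whether or not it appears in an edge.
    """

    n_vertices: int
    edges: np.ndarray  # (E, 2) int64, each row (i, j) with i < j, unique

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.n_vertices < 0:
            raise ValidationError("n_vertices must be >= 0")
        if self.edges.size:
            if self.edges.min() < 0 or self.edges.max() >= self.n_vertices:
                raise ValidationError("edge endpoint outside [0, n_vertices)")
            if not np.all(self.edges[:, 0] < self.edges[:, 1]):
                raise ValidationError("edges must be canonical (i < j)")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric boolean adjacency matrix as CSR."""
        if not self.edges.size:
            return sp.csr_matrix((self.n_vertices, self.n_vertices), dtype=np.int64)
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * self.n_edges, dtype=np.int64)
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_vertices, self.n_vertices)
        )


@dataclass
class VertexMetrics:
    """Per-vertex metric bundle: degree, triangles, clustering, PageRank, component."""

    d: np.ndarray
    tc: np.ndarray
    cc: np.ndarray
    pr: np.ndarray
    comp: np.ndarray


@dataclass
class GraphSummary:
    """N vertices, E edges, average degree K = 2E/N, density statistic S."""

    N: int
    E: int
    K: float
    S: float


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_edge_list(path: str | Path, n_vertices: int | None = None) -> SparseGraph:
    """Load a whitespace-separated integer edge list as an undirected simple graph.

    Lines hold ``i j`` or ``i j weight`` (the weight is ignored); ``#``
    lines are skipped, but a ``# n_vertices=V`` header is honoured when the
    caller does not pass ``n_vertices``.  Duplicate lines and both
    orientations of a pair collapse to one edge; self-loops are dropped
    with a logged count.  Gzip files (``.gz``) are transparent.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    pairs: list[tuple[int, int]] = []
    header_n: int | None = None
    n_self_loops = 0
    with opener(path, "rt") as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if token.startswith("n_vertices="):
                        try:
                            header_n = int(token.split("=", 1)[1])
                        except ValueError:
                            pass
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(f"expected at least 2 columns, got {line!r}", lineno)
            try:
                a, b = int(tokens[0]), int(tokens[1])
            except ValueError:
                raise EdgeListParseError(f"non-integer vertex id in {line!r}", lineno) from None
            if a < 0 or b < 0:
                raise ValidationError(f"negative vertex id on line {lineno}: {line!r}")
            if a == b:
                n_self_loops += 1
                continue
            pairs.append((min(a, b), max(a, b)))
    if n_self_loops:
        logger.info("load_edge_list: dropped %d self-loop(s)", n_self_loops)
    edges = np.unique(np.asarray(pairs, dtype=np.int64).reshape(-1, 2), axis=0)
    if n_vertices is None:
        n_vertices = header_n
    if n_vertices is None:
        n_vertices = int(edges.max()) + 1 if edges.size else 0
    return SparseGraph(n_vertices=n_vertices, edges=edges)


def from_weighted_edges(edges: WeightedEdgeList) -> SparseGraph:
    """Unweighted view of a thresholded edge list (metrics ignore r)."""
    pairs = np.column_stack([edges.i, edges.j])
    return SparseGraph(n_vertices=edges.n_vertices, edges=pairs)


# ---------------------------------------------------------------------------
# per-vertex metrics
# ---------------------------------------------------------------------------

def degrees(g: SparseGraph) -> np.ndarray:
    """Number of incident edges per vertex (sums to 2E)."""
    d = np.zeros(g.n_vertices, dtype=np.int64)
    if g.edges.size:
        np.add.at(d, g.edges[:, 0], 1)
        np.add.at(d, g.edges[:, 1], 1)
    return d


def connected_components(g: SparseGraph) -> np.ndarray:
    """Component label per vertex; the label is the component's minimum vertex id."""
    if g.n_vertices == 0:
        return np.empty(0, dtype=np.int64)
    _, raw = csgraph.connected_components(g.adjacency(), directed=False)
    min_member = np.full(raw.max() + 1, g.n_vertices, dtype=np.int64)
    np.minimum.at(min_member, raw, np.arange(g.n_vertices))
    return min_member[raw]


def triangle_counts(g: SparseGraph) -> np.ndarray:
    """Number of distinct triangles through each vertex.

    Uses (A @ A) .* A row sums: entry (v, w) of A^2 counts common neighbours
    of v and w, so summing over the neighbours w of v counts each triangle
    at v twice.
    """
    if g.n_vertices == 0:
        return np.empty(0, dtype=np.int64)
    A = g.adjacency()
    paths2 = (A @ A).multiply(A)
    tc2 = np.asarray(paths2.sum(axis=1)).ravel()
    return (tc2 // 2).astype(np.int64)


def local_clustering(d: np.ndarray, tc: np.ndarray) -> np.ndarray:
    """Local clustering coefficient ``tc / (d (d-1) / 2)``; 0 where degree < 2."""
    d = np.asarray(d, dtype=np.float64)
    tc = np.asarray(tc, dtype=np.float64)
    if d.shape != tc.shape:
        raise ValidationError("degree and triangle-count vectors differ in length")
    possible = d * (d - 1) / 2.0
    cc = np.zeros_like(d)
    ok = d >= 2
    cc[ok] = tc[ok] / possible[ok]
    return cc


def pagerank(
    g: SparseGraph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """PageRank by power iteration; each undirected edge is two directed edges.

    Iterates ``p' = (1 - alpha)/N + alpha * (A @ (p / deg) + dangling/N)``
    until the L1 change drops below ``tol``.  Dangling (isolated) vertices
    spread their mass uniformly.  The result sums to 1.
    """
    N = g.n_vertices
    if N == 0:
        return np.empty(0, dtype=np.float64)
    A = g.adjacency().astype(np.float64)
    deg = degrees(g).astype(np.float64)
    dangling = deg == 0
    safe_deg = np.where(dangling, 1.0, deg)
    p = np.full(N, 1.0 / N)
    residual = np.inf
    for _ in range(max_iter):
        share = np.where(dangling, 0.0, p) / safe_deg
        dangling_mass = p[dangling].sum()
        p_new = (1.0 - damping) / N + damping * (A @ share + dangling_mass / N)
        residual = float(np.abs(p_new - p).sum())
        p = p_new
        if residual < tol:
            return p
    raise ConvergenceError(
        f"PageRank did not converge in {max_iter} iterations", residual
    )


def compute_vertex_metrics(
    g: SparseGraph,
    damping: float = 0.85,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> VertexMetrics:
    """All per-vertex metrics in one pass over the graph."""
    d = degrees(g)
    tc = triangle_counts(g)
    return VertexMetrics(
        d=d,
        tc=tc,
        cc=local_clustering(d, tc),
        pr=pagerank(g, damping=damping, tol=tol, max_iter=max_iter),
        comp=connected_components(g),
    )


# ---------------------------------------------------------------------------
# edge-density statistic and threshold selection
# ---------------------------------------------------------------------------

def edge_density_statistic(E: int, N: int) -> GraphSummary:
    """S = log E / log K with K = 2E/N; defined only for E >= 1 and K > 1."""
    if N < 1:
        raise ValidationError("N must be >= 1")
    if E < 1:
        raise StatisticUndefinedError("S undefined for E = 0")
    K = 2.0 * E / N
    if K <= 1.0:
        raise StatisticUndefinedError(f"S undefined for average degree K = {K} <= 1")
    return GraphSummary(N=N, E=E, K=K, S=float(np.log(E) / np.log(K)))


def select_threshold(
    z: StandardizedTable,
    target_S: float,
    grid: np.ndarray,
) -> tuple[float, GraphSummary]:
    """Pick the largest grid threshold whose edge-density statistic meets target_S.

    Lowering the threshold can only add edges, so both E and S move
    monotonically along the grid; the selection scans thresholds from the
    largest down and returns the first whose S >= target_S (ties toward the
    larger threshold).  Edge counts for the whole grid are accumulated in a
    single tiled pass over the correlation matrix.
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValidationError("thresholds must lie in (0, 1)")
    asc = np.sort(grid)  # ascending for searchsorted
    from .connectivity import plan_tiles  # local import to avoid cycle at module load

    V = z.n_voxels
    plan = plan_tiles(V, 8, max(V * 8, 64 * 2**20))
    counts = np.zeros(asc.size, dtype=np.int64)  # counts[k] = #{|r| >= asc[k]}
    cols = np.arange(V)
    for start, end in plan.blocks:
        tile = correlation_tile(z, (start, end))
        rows_global = np.arange(start, end)
        upper = cols[None, :] > rows_global[:, None]
        absr = np.sort(np.abs(tile[upper]))
        counts += absr.size - np.searchsorted(absr, asc, side="left")

    attainable: list[float] = []
    for thr, E in zip(asc[::-1], counts[::-1]):  # descending thresholds
        if E < 1:
            continue
        K = 2.0 * E / V
        if K <= 1.0:
            continue
        summary = edge_density_statistic(int(E), V)
        attainable.append(summary.S)
        if summary.S >= target_S:
            return float(thr), summary
    if attainable:
        raise ThresholdRangeError(
            f"target S = {target_S} unattainable on grid; attainable S range "
            f"[{min(attainable):.4f}, {max(attainable):.4f}]"
        )
    raise ThresholdRangeError(
        f"target S = {target_S} unattainable: no grid threshold yields K > 1"
    )
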