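"""Tiled voxelwise correlation and thresholded sparse graph construction.

The full V x V Pearson correlation matrix of voxel time series is far too
large to materialize for whole-brain data (for ~228k in-brain voxels at
double precision it would occupy ~390 GB), but each *row block* of the
matrix is cheap: after columnwise standardization, a block of correlations
is a single matrix product ``Z[:, a:b].T @ Z / (T - 1)``.  This module plans
row blocks under an explicit byte budget, computes them one at a time, and
streams the entries that survive an absolute-correlation threshold into a
sparse undirected edge list.  The streamed output is exactly independent of
the tile plan.

Zero-variance (constant) voxel time series have no defined correlation; they
are flagged during standardization and their correlation against everything
is 0, so they simply become isolated vertices rather than NaN sources.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import CapacityError, ValidationError
from .nifti_io import VoxelTable

logger = logging.getLogger(__name__)

__all__ = [
    "TilePlan",
    "WeightedEdgeList",
    "StandardizedTable",
    "standardize",
    "plan_tiles",
    "memory_footprint",
    "correlation_tile",
    "column_cosine_tile",
    "threshold_stream",
    "write_edge_list",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TilePlan:
    """Partition of the V x V correlation matrix into row-block tiles.

    Each block ``[start, end)`` of rows yields a dense ``(end-start) x V``
    tile of at most ``tile_budget_bytes`` bytes.
    """

    n_voxels: int
    bytes_per_element: int
    tile_budget_bytes: int
    blocks: list[tuple[int, int]]

    def __post_init__(self):
        if not self.blocks:
            raise ValidationError("tile plan has no blocks")
        expected_start = 0
        for start, end in self.blocks:
            if start != expected_start or end <= start:
                raise ValidationError("blocks must partition [0, n_voxels) in order")
            if (end - start) * self.n_voxels * self.bytes_per_element > self.tile_budget_bytes:
                raise ValidationError("block exceeds the tile byte budget")
            expected_start = end
        if expected_start != self.n_voxels:
            raise ValidationError("blocks do not cover [0, n_voxels)")

    @property
    def n_tiles(self) -> int:
        return len(self.blocks)


@dataclass
class WeightedEdgeList:
    """Sparse undirected graph as (i, j, r) triples surviving |r| >= threshold.

    Invariant: ``i < j`` for every record (each unordered pair once, no
    self-edges); ``r`` keeps its sign even though thresholding is on |r|.
    """

    i: np.ndarray
    j: np.ndarray
    r: np.ndarray
    threshold: float
    n_vertices: int

    def __post_init__(self):
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.r = np.asarray(self.r, dtype=np.float64)
        if not (self.i.shape == self.j.shape == self.r.shape):
            raise ValidationError("i, j, r must have identical shapes")
        if self.i.size and not np.all(self.i < self.j):
            raise ValidationError("edge records must satisfy i < j")

    @property
    def n_edges(self) -> int:
        return int(self.i.size)


@dataclass
class StandardizedTable:
    """A VoxelTable whose columns have mean 0 and (sample) sd 1.

    Constant input columns are set to all-zero and listed in
    ``zero_variance`` (column positions, not grid indices).
    """

    table: VoxelTable
    zero_variance: np.ndarray  # column positions with sd == 0

    @property
    def data(self) -> np.ndarray:
        return self.table.data

    @property
    def n_timepoints(self) -> int:
        return self.table.n_timepoints

    @property
    def n_voxels(self) -> int:
        return self.table.n_voxels


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def standardize(table: VoxelTable) -> StandardizedTable:
    """Columnwise z-scoring with sample standard deviation (ddof=1).

    After this, the Pearson correlation of columns a and b is the scaled dot
    product ``z_a . z_b / (T - 1)``, which is what the tiled stage computes.
    """
    if table.n_timepoints < 2:
        raise ValidationError("standardize requires at least 2 time points")
    data = np.asarray(table.data, dtype=np.float64)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(sd == 0)
    centered = data - mean
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = centered / safe_sd
    if zero_var.size:
        z[:, zero_var] = 0.0
        logger.info("standardize: %d zero-variance voxel(s) set to 0", zero_var.size)
    out = VoxelTable(
        data=z,
        index_map=table.index_map,
        grid_dims=table.grid_dims,
        affine=table.affine,
        tr_seconds=table.tr_seconds,
        source_path=table.source_path,
    )
    return StandardizedTable(table=out, zero_variance=zero_var)


def plan_tiles(n_voxels: int, bytes_per_element: int, tile_budget_bytes: int) -> TilePlan:
    """Partition the correlation matrix rows into blocks fitting the budget.

    Block height is ``floor(budget / (V * bytes_per_element))``; the last
    block may be shorter.
    """
    if n_voxels < 1:
        raise ValidationError("n_voxels must be >= 1")
    row_bytes = n_voxels * bytes_per_element
    if tile_budget_bytes < row_bytes:
        raise CapacityError(
            f"tile budget {tile_budget_bytes} B cannot hold one {row_bytes} B row"
        )
    height = tile_budget_bytes // row_bytes
    starts = list(range(0, n_voxels, height))
    blocks = [(s, min(s + height, n_voxels)) for s in starts]
    return TilePlan(
        n_voxels=n_voxels,
        bytes_per_element=bytes_per_element,
        tile_budget_bytes=tile_budget_bytes,
        blocks=blocks,
    )


def memory_footprint(n_voxels: int, bytes_per_element: int = 8) -> int:
    """Bytes a dense V x V correlation matrix would occupy (symmetry unused)."""
    if n_voxels < 1:
        raise ValidationError("n_voxels must be >= 1")
    return n_voxels * n_voxels * bytes_per_element


def correlation_tile(z: StandardizedTable, block: tuple[int, int]) -> np.ndarray:
    """Dense correlation tile for rows ``block`` against all columns.

    ``out[a, b] = r(voxel block[0]+a, voxel b)``, clipped to [-1, 1].  Rows
    and columns of zero-variance voxels are exactly 0.
    """
    start, end = block
    if not (0 <= start < end <= z.n_voxels):
        raise ValidationError(f"block {block} out of range for {z.n_voxels} voxels")
    T = z.n_timepoints
    # One matrix-vector product per row: the arithmetic for a given row is
    # identical whatever the block height, so results are bit-identical
    # across tile plans (a blocked matrix-matrix product would not be).
    tile = np.empty((end - start, z.n_voxels))
    for a, g in enumerate(range(start, end)):
        tile[a, :] = z.data[:, g] @ z.data
    tile /= T - 1
    np.clip(tile, -1.0, 1.0, out=tile)
    return tile


def column_cosine_tile(table: VoxelTable, block: tuple[int, int]) -> np.ndarray:
    """Cosine similarity of column blocks: ``dot(a, b) / (|a| |b|)``.

    All-zero columns get similarity 0 by convention.  On a standardized
    table this coincides with Pearson correlation.
    """
    start, end = block
    data = np.asarray(table.data, dtype=np.float64)
    if not (0 <= start < end <= data.shape[1]):
        raise ValidationError(f"block {block} out of range for {data.shape[1]} voxels")
    norms = np.linalg.norm(data, axis=0)
    safe = np.where(norms == 0, 1.0, norms)
    tile = (data[:, start:end].T @ data) / np.outer(safe[start:end], safe)
    tile[norms[start:end] == 0, :] = 0.0
    tile[:, norms == 0] = 0.0
    np.clip(tile, -1.0, 1.0, out=tile)
    return tile


def threshold_stream(
    z: StandardizedTable,
    plan: TilePlan,
    threshold: float,
) -> WeightedEdgeList:
    """Stream the tiled correlation matrix through an |r| >= threshold filter.

    Emits exactly the pairs i < j with |r_ij| >= threshold, each once with
    its signed r.  The output is independent of the tile plan: tiling is a
    memory strategy, not a modelling choice.
    """
    if not (0.0 < threshold < 1.0):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if plan.n_voxels != z.n_voxels:
        raise ValidationError(
            f"plan is for {plan.n_voxels} voxels but table has {z.n_voxels}"
        )
    ii: list[np.ndarray] = []
    jj: list[np.ndarray] = []
    rr: list[np.ndarray] = []
    cols = np.arange(z.n_voxels)
    for start, end in plan.blocks:
        tile = correlation_tile(z, (start, end))
        rows_global = np.arange(start, end)
        keep = (np.abs(tile) >= threshold) & (cols[None, :] > rows_global[:, None])
        a, b = np.nonzero(keep)
        ii.append(rows_global[a])
        jj.append(b)
        rr.append(tile[a, b])
    i = np.concatenate(ii) if ii else np.empty(0, dtype=np.int64)
    j = np.concatenate(jj) if jj else np.empty(0, dtype=np.int64)
    r = np.concatenate(rr) if rr else np.empty(0, dtype=np.float64)
    return WeightedEdgeList(i=i, j=j, r=r, threshold=threshold, n_vertices=z.n_voxels)


# ---------------------------------------------------------------------------
# edge-list text output
# ---------------------------------------------------------------------------

def write_edge_list(
    edges: WeightedEdgeList,
    path: str | Path,
    source: str = "",
    graphx_compat: bool = False,
    extra_header: dict | None = None,
) -> Path:
    """Write an edge list as plain text, one ``i j r`` line per edge.

    Vertex ids are 0-based x-fastest linear grid indices.  ``#`` header
    lines record n_vertices, threshold and provenance.  With
    ``graphx_compat`` only ``i j`` is written (the two-column dialect that
    plain graph loaders expect).  A ``.gz`` suffix triggers gzip output.
    """
    path = Path(path)
    if path.suffix == ".gz":
        # fixed mtime and no embedded filename: identical edges => identical bytes
        def opener(p, _mode):
            import io

            return io.TextIOWrapper(
                gzip.GzipFile(filename="", mode="wb", fileobj=open(p, "wb"), mtime=0)
            )
    else:
        opener = open
    with opener(path, "wt") as f:
        f.write("# voxelgraph edge list\n")
        f.write("# vertex ids: 0-based x-fastest linear index of mask grid\n")
        f.write(f"# n_vertices={edges.n_vertices} n_edges={edges.n_edges} "
                f"threshold={edges.threshold!r}\n")
        if source:
            f.write(f"# source={source}\n")
        for key, value in (extra_header or {}).items():
            f.write(f"# {key}={value}\n")
        if graphx_compat:
            for a, b in zip(edges.i, edges.j):
                f.write(f"{a} {b}\n")
        else:
            for a, b, w in zip(edges.i, edges.j, edges.r):
                f.write(f"{a} {b} {w:.10g}\n")
    return path
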