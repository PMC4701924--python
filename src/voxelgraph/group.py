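"""Group-level stacking of subject tables and truncated SVD.

Multiple subjects sharing one brain mask are stacked row-wise (time points
concatenated) into a single group matrix with voxels in columns, on which a
truncated SVD — optionally after per-voxel centering, turning it into PCA —
extracts the dominant spatiotemporal components.  The truncated solver is
iterative (Lanczos), never a dense decomposition, since the voxel dimension
of whole-brain data rules out dense factorization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .errors import AlignmentError, ValidationError
from .nifti_io import VoxelTable

__all__ = ["GroupMatrix", "group_stack", "truncated_svd"]


@dataclass
class GroupMatrix:
    """Row-stacked subject tables: (sum_s T_s) x V, voxels in columns.

    ``subject_boundaries`` holds the cumulative row offsets, so subject s
    occupies rows ``[boundaries[s], boundaries[s+1])``.
    """

    data: np.ndarray
    subject_boundaries: np.ndarray  # (n_subjects + 1,) row offsets
    index_map: np.ndarray

    @property
    def n_subjects(self) -> int:
        return int(self.subject_boundaries.size - 1)

    def subject_rows(self, s: int) -> np.ndarray:
        lo, hi = self.subject_boundaries[s], self.subject_boundaries[s + 1]
        return self.data[lo:hi]


def group_stack(tables: list[VoxelTable]) -> GroupMatrix:
    """Concatenate subjects' time points row-wise over a shared voxel set.

    All tables must have identical index maps (same mask); column v keeps
    the meaning "voxel index_map[v]" across the whole group.
    """
    if not tables:
        raise ValidationError("group_stack requires at least one table")
    ref = tables[0].index_map
    for s, table in enumerate(tables[1:], start=1):
        if table.index_map.shape != ref.shape or not np.array_equal(table.index_map, ref):
            if table.index_map.shape != ref.shape:
                raise AlignmentError(
                    f"subject {s} has {table.index_map.size} voxels, expected {ref.size}"
                )
            first_bad = int(np.flatnonzero(table.index_map != ref)[0])
            raise AlignmentError(
                f"subject {s} voxel {first_bad}: index {table.index_map[first_bad]} "
                f"!= reference {ref[first_bad]}"
            )
    boundaries = np.concatenate([[0], np.cumsum([t.n_timepoints for t in tables])])
    return GroupMatrix(
        data=np.vstack([t.data for t in tables]),
        subject_boundaries=boundaries.astype(np.int64),
        index_map=ref.copy(),
    )


def truncated_svd(
    m: GroupMatrix,
    k: int,
    center: bool = False,
    seed: int | None = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Top-k singular triplets of the group matrix.

    Returns ``(singular_values, left, right)`` with singular values
    non-negative and non-increasing, ``left`` of shape rows x k and
    ``right`` of shape V x k, both with orthonormal columns.  With
    ``center=True`` columns are mean-centered first (PCA).  The starting
    vector of the Lanczos iteration is seeded for reproducibility.
    """
    X = np.asarray(m.data, dtype=np.float64)
    min_dim = min(X.shape)
    if not (1 <= k <= min_dim):
        raise ValidationError(f"k must be in [1, {min_dim}], got {k}")
    if center:
        X = X - X.mean(axis=0)
    if k == min_dim:
        # Lanczos (ARPACK) requires k < min(shape); the full-rank request only
        # arises for small matrices, where LAPACK is exact and cheap.
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        return s[:k], U[:, :k], Vt[:k].T
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(min_dim)
    U, s, Vt = spla.svds(X, k=k, v0=v0)
    order = np.argsort(s)[::-1]
    return s[order], U[:, order], Vt[order].T
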