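"""Masked NIfTI-1 input/output for voxelwise connectivity analysis.

Reads 4D BOLD time series into a time x voxel matrix restricted to a binary
brain mask, in bounded-memory chunks of volumes, and writes per-voxel metric
vectors back as 3D NIfTI maps.

Conventions
-----------
* The in-memory orientation is **time x voxel**: rows are volumes (time
  points), columns are voxel time series.  All downstream stages assume it.
* Voxels are identified by their 0-based, first-axis-fastest (x-fastest)
  linear index into the mask grid: ``x + nx*(y + ny*z)``.  These indices are
  the graph vertex ids, so a vertex in any edge list or metrics table can be
  mapped back to a grid coordinate without extra metadata.
* Intensities are promoted to 64-bit floats on read and NIfTI
  ``scl_slope``/``scl_inter`` scaling is applied, so correlations downstream
  are computed on calibrated values in double precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .errors import FormatError, GeometryError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BrainMask",
    "VoxelTable",
    "MetricMap",
    "linear_index",
    "unravel_index",
    "load_mask",
    "read_masked",
    "write_metric_map",
    "save_table",
    "load_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class BrainMask:
    """Binary 3D brain mask: which grid cells are in-brain, plus geometry.

    Any strictly positive stored value counts as in-mask (standard binary
    masks contain 1.0, but probabilistic or labelled masks are tolerated).
    """

    grid_dims: tuple[int, int, int]
    affine: np.ndarray
    in_mask: np.ndarray  # boolean, shape == grid_dims

    def __post_init__(self):
        self.in_mask = np.asarray(self.in_mask, dtype=bool)
        if self.in_mask.shape != tuple(self.grid_dims):
            raise GeometryError(
                f"mask array shape {self.in_mask.shape} != grid_dims {self.grid_dims}"
            )
        if self.n_voxels < 1:
            raise ValidationError("mask is empty: no in-mask voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.in_mask.sum())

    @property
    def index_map(self) -> np.ndarray:
        """Sorted x-fastest linear indices of the in-mask cells."""
        return np.flatnonzero(self.in_mask.ravel(order="F"))


@dataclass
class VoxelTable:
    """Time x voxel matrix of BOLD values with a map back to grid coordinates.

    ``data[t, v]`` is the intensity at volume ``t`` for the voxel whose
    x-fastest linear grid index is ``index_map[v]``.
    """

    data: np.ndarray  # (T, V) float
    index_map: np.ndarray  # (V,) int64, strictly increasing
    grid_dims: tuple[int, int, int]
    affine: np.ndarray
    tr_seconds: float | None = None
    source_path: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.index_map = np.asarray(self.index_map, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValidationError("VoxelTable data must be 2D (time x voxel)")
        if self.data.shape[1] != self.index_map.shape[0]:
            raise ValidationError(
                f"data has {self.data.shape[1]} columns but index_map has "
                f"{self.index_map.shape[0]} entries"
            )
        if self.index_map.size > 1 and not np.all(np.diff(self.index_map) > 0):
            raise ValidationError("index_map must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


@dataclass
class MetricMap:
    """One real value per in-mask voxel, ready to be written as a 3D map."""

    values: np.ndarray
    fill_value: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValidationError("MetricMap values must be a 1D vector")


# ---------------------------------------------------------------------------
# voxel <-> vertex identity
# ---------------------------------------------------------------------------

def linear_index(x: int, y: int, z: int, grid_dims) -> int:
    """0-based x-fastest linearization: ``x + nx*(y + ny*z)``.

    This is the voxel/vertex identifier used throughout the package.
    """
    nx, ny, nz = (int(d) for d in grid_dims)
    x, y, z = int(x), int(y), int(z)
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise ValidationError(
            f"coordinate ({x},{y},{z}) out of range for grid {tuple(grid_dims)}"
        )
    return x + nx * (y + ny * z)


def unravel_index(idx: int, grid_dims) -> tuple[int, int, int]:
    """Inverse of :func:`linear_index`."""
    nx, ny, nz = (int(d) for d in grid_dims)
    idx = int(idx)
    if not (0 <= idx < nx * ny * nz):
        raise ValidationError(f"linear index {idx} out of range for grid {tuple(grid_dims)}")
    x = idx % nx
    y = (idx // nx) % ny
    z = idx // (nx * ny)
    return x, y, z


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _choose_affine(img) -> np.ndarray:
    """Pick the image affine, preferring qform when qform and sform disagree."""
    hdr = img.header
    try:
        sform_code = int(hdr["sform_code"])
        qform_code = int(hdr["qform_code"])
    except (KeyError, TypeError):  # non-NIfTI header
        return img.affine
    if sform_code > 0 and qform_code > 0:
        qform = img.get_qform()
        sform = img.get_sform()
        if not np.allclose(qform, sform, atol=1e-4):
            logger.warning(
                "qform and sform disagree in %s; using qform",
                getattr(img, "file_map", None) and img.get_filename(),
            )
            return qform
    return img.affine


def load_mask(mask_path: str | Path) -> BrainMask:
    """Load a 3D NIfTI brain mask; any value > 0 is in-mask."""
    img = nib.load(str(mask_path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"mask {mask_path} is {data.ndim}D, expected 3D")
    return BrainMask(
        grid_dims=tuple(int(d) for d in data.shape),
        affine=_choose_affine(img),
        in_mask=data > 0,
    )


def read_masked(
    image_path: str | Path,
    mask_path: str | Path,
    chunk_volumes: int = 32,
) -> VoxelTable:
    """Read a masked 4D NIfTI BOLD image into a :class:`VoxelTable`.

    Volumes are read in chunks of ``chunk_volumes`` so the high-water memory
    mark is bounded by one chunk of volumes plus the output matrix, never the
    whole uncompressed 4D image.  The result is exactly identical for every
    chunk size.

    Parameters
    ----------
    image_path:
        4D NIfTI-1 image (optionally .nii.gz).
    mask_path:
        3D NIfTI mask on the same grid; cells > 0 are read.
    chunk_volumes:
        Number of volumes loaded per iteration (>= 1).
    """
    if chunk_volumes < 1:
        raise ValidationError(f"chunk_volumes must be >= 1, got {chunk_volumes}")
    img = nib.load(str(image_path))
    if len(img.shape) != 4:
        raise FormatError(f"image {image_path} is {len(img.shape)}D, expected 4D")
    mask = load_mask(mask_path)
    if tuple(img.shape[:3]) != tuple(mask.grid_dims):
        raise GeometryError(
            f"image grid {tuple(img.shape[:3])} != mask grid {tuple(mask.grid_dims)}"
        )

    n_volumes = int(img.shape[3])
    index_map = mask.index_map
    n_grid = int(np.prod(mask.grid_dims))
    out = np.empty((n_volumes, index_map.size), dtype=np.float64)

    for start in range(0, n_volumes, chunk_volumes):
        stop = min(start + chunk_volumes, n_volumes)
        # dataobj slicing reads only these volumes and applies scl scaling
        chunk = np.asanyarray(img.dataobj[..., start:stop]).astype(np.float64, copy=False)
        flat = chunk.reshape((n_grid, stop - start), order="F")
        out[start:stop, :] = flat[index_map, :].T

    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else None
    return VoxelTable(
        data=out,
        index_map=index_map,
        grid_dims=tuple(mask.grid_dims),
        affine=_choose_affine(img),
        tr_seconds=tr,
        source_path=str(image_path),
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_metric_map(
    metric: MetricMap,
    mask: BrainMask,
    out_path: str | Path,
    dtype=np.float32,
) -> Path:
    """Write a per-voxel metric vector as a 3D NIfTI map on the mask grid.

    In-mask cells receive ``metric.values`` (in index_map order); everything
    else receives ``metric.fill_value``.  The mask affine is preserved.
    """
    if metric.values.shape[0] != mask.n_voxels:
        raise ValidationError(
            f"metric has {metric.values.shape[0]} values but mask has "
            f"{mask.n_voxels} voxels"
        )
    vol = np.full(int(np.prod(mask.grid_dims)), metric.fill_value, dtype=dtype)
    vol[mask.index_map] = metric.values.astype(dtype, copy=False)
    vol = vol.reshape(mask.grid_dims, order="F")
    img = nib.Nifti1Image(vol, mask.affine)
    img.header.set_data_dtype(dtype)
    out_path = Path(out_path)
    nib.save(img, str(out_path))
    return out_path


def extract_metric(map_path: str | Path, mask: BrainMask) -> np.ndarray:
    """Read back the in-mask values of a metric map, in index_map order."""
    img = nib.load(str(map_path))
    data = np.squeeze(np.asanyarray(img.dataobj))
    if data.shape != tuple(mask.grid_dims):
        raise GeometryError(
            f"map grid {data.shape} != mask grid {tuple(mask.grid_dims)}"
        )
    return data.ravel(order="F")[mask.index_map]


# ---------------------------------------------------------------------------
# HDF5 table store
# ---------------------------------------------------------------------------

def save_table(table: VoxelTable, path: str | Path) -> Path:
    """Persist a VoxelTable to HDF5 (datasets ``data`` and ``index_map``)."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=table.data)
        f.create_dataset("index_map", data=table.index_map)
        f.attrs["grid_dims"] = np.asarray(table.grid_dims, dtype=np.int64)
        f.attrs["affine"] = np.asarray(table.affine, dtype=np.float64)
        f.attrs["tr_seconds"] = -1.0 if table.tr_seconds is None else table.tr_seconds
        f.attrs["source_path"] = table.source_path
        f.attrs["vertex_id_convention"] = "0-based x-fastest linear index of mask grid"
    return path


def load_table(path: str | Path) -> VoxelTable:
    with h5py.File(path, "r") as f:
        tr = float(f.attrs["tr_seconds"])
        return VoxelTable(
            data=f["data"][()],
            index_map=f["index_map"][()],
            grid_dims=tuple(int(d) for d in f.attrs["grid_dims"]),
            affine=np.asarray(f.attrs["affine"], dtype=np.float64),
            tr_seconds=None if tr < 0 else tr,
            source_path=str(f.attrs["source_path"]),
        )
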