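"""Core in-memory containers shared by every pipeline stage.

The subject-level unit of input is a :class:`BoldImage` (4D intensity array
plus voxel-to-mm affine and repetition time).  All connectivity math runs on
a :class:`VoxelTimeSeries`, the masked voxels-by-time matrix together with
the mm coordinate of each voxel center.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["BoldImage", "VoxelTimeSeries", "extract_timeseries"]


@dataclass
class BoldImage:
    """A 4D BOLD volume with its spatial affine and repetition time.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, T)
        Voxel intensities.
    affine : ndarray, shape (4, 4)
        Voxel-index to mm homogeneous transform (NIfTI convention).
    tr_seconds : float
        Repetition time in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if not self.tr_seconds > 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def voxel_coords_mm(voxel_index: np.ndarray, grid_shape, affine: np.ndarray) -> np.ndarray:
    """mm coordinates of voxel centers for flat indices into a 3D grid."""
    ijk = np.column_stack(np.unravel_index(np.asarray(voxel_index), grid_shape))
    hom = np.column_stack([ijk, np.ones(len(ijk))])
    return (hom @ affine.T)[:, :3]


@dataclass
class VoxelTimeSeries:
    """Masked voxel-by-time matrix with spatial metadata.

    ``values[i]`` is the time series of the voxel whose flat grid index is
    ``voxel_index[i]`` and whose center sits at ``coords_mm[i]``.  Zero
    variance voxels are dropped at extraction time (and counted), so every
    retained row supports a Pearson correlation.
    """

    values: np.ndarray          # (V, T)
    coords_mm: np.ndarray       # (V, 3)
    voxel_index: np.ndarray     # (V,) flat indices into grid
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    n_dropped: int = 0
    mask_source: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be (voxels, time)")
        if not np.all(np.isfinite(self.coords_mm)):
            raise ValueError("coords_mm must be finite")

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "VoxelTimeSeries":
        """Copy of this container with a new value matrix (same geometry)."""
        if values.shape[0] != self.n_voxels:
            raise ValueError("voxel dimension mismatch")
        return replace(self, values=np.asarray(values, dtype=float))

    def to_map(self, per_voxel: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter one value per voxel back into a 3D grid."""
        out = np.full(self.grid_shape, fill, dtype=float)
        out.flat[self.voxel_index] = per_voxel
        return out

    def mask_array(self) -> np.ndarray:
        m = np.zeros(self.grid_shape, dtype=bool)
        m.flat[self.voxel_index] = True
        return m


def extract_timeseries(img: BoldImage, mask: np.ndarray, mask_source: str = "") -> VoxelTimeSeries:
    """Pull the in-mask voxel time series out of a 4D image.

    Voxels with zero temporal variance cannot enter correlation analysis and
    are dropped (the count is retained on the result and logged).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.grid_shape:
        raise ValueError(f"mask shape {mask.shape} does not match image grid {img.grid_shape}")
    flat = np.flatnonzero(mask.ravel())
    if flat.size == 0:
        raise ValueError("mask selects no voxels")
    values = img.data.reshape(-1, img.n_volumes)[flat].astype(float)
    variances = values.var(axis=1)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropping %d zero-variance voxels from mask", n_dropped)
        flat = flat[keep]
        values = values[keep]
    coords = voxel_coords_mm(flat, img.grid_shape, img.affine)
    return VoxelTimeSeries(
        values=values,
        coords_mm=coords,
        voxel_index=flat,
        grid_shape=img.grid_shape,
        affine=img.affine,
        n_dropped=n_dropped,
        mask_source=mask_source,
    )
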