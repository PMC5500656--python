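"""Seed-based functional connectivity maps.

A seed is a small sphere (default 6 mm diameter) centered at a peak
coordinate — typically the peak of a cluster surviving group inference on
the FCS maps.  The seed signal is the unweighted mean time series over the
in-mask voxels whose centers fall within the sphere (boundary inclusive);
the output map is the Fisher-z transformed Pearson correlation between the
seed signal and every masked voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import VoxelTimeSeries
from .fcs import fisher_z

__all__ = ["SeedSpec", "sphere_voxels", "seed_fc_map"]


@dataclass
class SeedSpec:
    center_mm: np.ndarray
    diameter_mm: float = 6.0
    label: str = ""

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float).reshape(3)
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")


def sphere_voxels(seed: SeedSpec, ts: VoxelTimeSeries) -> np.ndarray:
    """Flat grid indices of the in-mask voxels inside the seed sphere.

    Membership is inclusive at the boundary (distance <= radius); on a 3 mm
    grid a 6 mm sphere centered on a voxel therefore holds 7 voxels (the
    center and its six face neighbours at exactly 3 mm).
    """
    d = np.linalg.norm(ts.coords_mm - seed.center_mm, axis=1)
    inside = d <= seed.diameter_mm / 2.0
    if not inside.any():
        j = int(np.argmin(d))
        near = ts.coords_mm[j]
        raise ValueError(
            f"seed {seed.label or seed.center_mm} intersects no mask voxel; "
            f"nearest mask voxel center is {near} at {d[j]:.1f} mm")
    return ts.voxel_index[inside]


def seed_fc_map(ts: VoxelTimeSeries, seed_voxels: np.ndarray
                ) -> tuple[np.ndarray, dict]:
    """Fisher-z map of correlation between the seed mean signal and every
    masked voxel.

    Returns the 3D z-map and a sidecar dict flagging the seed's own voxels
    (whose values include the seed-in-seed correlation).
    """
    seed_voxels = np.asarray(seed_voxels)
    pos = {v: i for i, v in enumerate(ts.voxel_index)}
    try:
        rows = np.array([pos[int(v)] for v in seed_voxels])
    except KeyError as e:
        raise ValueError(f"seed voxel {e} is not inside the analysis mask") from None
    seed_sig = ts.values[rows].mean(axis=0)
    seed_sig = seed_sig - seed_sig.mean()
    sd = seed_sig.std()
    if sd == 0:
        raise ValueError("seed signal has zero variance")
    seed_sig /= sd

    X = ts.values - ts.values.mean(axis=1, keepdims=True)
    vsd = X.std(axis=1)
    if np.any(vsd == 0):
        raise ValueError("zero-variance voxel in time series")
    X /= vsd[:, None]
    r = (X @ seed_sig) / ts.n_timepoints
    z = fisher_z(r)
    sidecar = {
        "seed_voxel_index": [int(v) for v in seed_voxels],
        "n_seed_voxels": int(len(seed_voxels)),
    }
    return ts.to_map(z), sidecar
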