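"""Voxel-wise functional connectivity strength (FCS) maps.

FCS is a weighted degree-centrality measure: for each gray-matter voxel,
the sum of Fisher-z transformed Pearson correlations with every other
gray-matter voxel, keeping only positive correlations above a threshold
(default r > 0.2).  The sum is partitioned by anatomical distance into a
long-range part (voxel pairs more than ``cutoff_mm`` apart, 75 mm at full
brain scale) and a short-range part (pairs closer than the cutoff; exact
ties are assigned to short so the partition is exhaustive).  By
construction ``long + short == global`` exactly at every voxel.

Maps are left unsmoothed here; :func:`smooth_map` applies the usual 6 mm
FWHM Gaussian before group inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist, squareform

from .containers import VoxelTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["FcsMaps", "fisher_z", "fcs_maps", "fcs_threshold_sweep", "smooth_map",
           "smooth_fcs", "FWHM_TO_SIGMA", "R_CLIP"]

#: correlations are clipped to +/-(1 - 1e-7) before arctanh so duplicated
#: series cannot produce infinities
R_CLIP = 1.0 - 1e-7
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def fisher_z(r) -> np.ndarray | float:
    """Fisher r-to-z transform, arctanh(r), with clipping at +/-R_CLIP."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


@dataclass
class FcsMaps:
    """Per-subject long-range, short-range and global FCS maps (z-sum units)
    with the parameters that produced them."""

    long_fcs: np.ndarray
    short_fcs: np.ndarray
    global_fcs: np.ndarray
    r_threshold: float
    distance_cutoff_mm: float
    smoothed: bool = False
    fwhm_mm: float | None = None
    n_clipped: int = 0
    n_distance_ties: int = 0

    def map_for(self, which: str) -> np.ndarray:
        return {"long": self.long_fcs, "short": self.short_fcs,
                "global": self.global_fcs}[which]


def _correlation_matrix(values: np.ndarray) -> np.ndarray:
    X = values - values.mean(axis=1, keepdims=True)
    sd = X.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance voxel in time series")
    X /= sd[:, None]
    R = (X @ X.T) / X.shape[1]
    return R


def fcs_maps(ts: VoxelTimeSeries, r_threshold: float = 0.2,
             cutoff_mm: float = 75.0,
             distances: np.ndarray | None = None) -> FcsMaps:
    """Compute unsmoothed long/short/global FCS maps for one subject.

    ``distances`` may carry a precomputed voxel-pair distance matrix (mm)
    to amortize geometry across subjects sharing a mask.
    """
    if ts.n_voxels < 2:
        raise ValueError("need at least 2 voxels")
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 time points for a correlation")
    if not (0 < r_threshold < 1):
        raise ValueError("r_threshold must be in (0, 1)")

    R = _correlation_matrix(ts.values)
    n_clipped = int(np.count_nonzero(np.abs(R) > R_CLIP) - ts.n_voxels)  # off-diag
    Z = fisher_z(R)
    supra = (R > r_threshold)
    np.fill_diagonal(supra, False)
    contrib = np.where(supra, Z, 0.0)

    if distances is None:
        distances = squareform(pdist(ts.coords_mm))
    n_ties = int(np.count_nonzero(distances == cutoff_mm)) // 2  # unordered pairs
    if n_ties:
        logger.info("%d voxel pairs at exactly the %.6g mm cutoff assigned to "
                    "short range", n_ties, cutoff_mm)
    long_pairs = distances > cutoff_mm
    long_v = (contrib * long_pairs).sum(axis=1)
    short_v = (contrib * ~long_pairs).sum(axis=1)  # diagonal already zeroed
    global_v = long_v + short_v

    return FcsMaps(long_fcs=ts.to_map(long_v), short_fcs=ts.to_map(short_v),
                   global_fcs=ts.to_map(global_v), r_threshold=r_threshold,
                   distance_cutoff_mm=cutoff_mm, n_clipped=max(n_clipped, 0),
                   n_distance_ties=n_ties)


def fcs_threshold_sweep(ts: VoxelTimeSeries, thresholds=(0.1, 0.2, 0.3),
                        cutoff_mm: float = 75.0) -> dict[float, FcsMaps]:
    """FCS maps at several correlation thresholds (robustness analysis).

    Per-voxel FCS is non-increasing in the threshold because raising it can
    only remove positive suprathreshold terms from the sum.
    """
    thrs = sorted(set(float(t) for t in thresholds))
    if any(not (0 < t < 1) for t in thrs):
        raise ValueError("thresholds must lie in (0, 1)")
    D = squareform(pdist(ts.coords_mm))
    return {t: fcs_maps(ts, r_threshold=t, cutoff_mm=cutoff_mm, distances=D)
            for t in thrs}


def smooth_map(map3d: np.ndarray, fwhm_mm: float = 6.0,
               voxel_size_mm: float = 3.0) -> np.ndarray:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis.

    Zero padding outside the array (no mask renormalization); FWHM 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    map3d = np.asarray(map3d, dtype=float)
    if fwhm_mm == 0:
        return map3d.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    return gaussian_filter(map3d, sigma=sigma_vox, mode="constant", cval=0.0)


def smooth_fcs(maps: FcsMaps, fwhm_mm: float = 6.0,
               voxel_size_mm: float = 3.0) -> FcsMaps:
    """Smooth the long and short maps; the global map is recomputed as
    their sum so the partition identity survives smoothing exactly."""
    long_s = smooth_map(maps.long_fcs, fwhm_mm, voxel_size_mm)
    short_s = smooth_map(maps.short_fcs, fwhm_mm, voxel_size_mm)
    return replace(maps, long_fcs=long_s, short_fcs=short_s,
                   global_fcs=long_s + short_s, smoothed=True, fwhm_mm=fwhm_mm)
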