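import numpy as np
import pytest

import rsfcs
from rsfcs.pipeline import AnalysisParams, preprocess_subject


def fcs_bruteforce(values, coords_mm, r_threshold, cutoff_mm):
    """Independent O(V^2) double-loop FCS oracle.

    Computes each pairwise Pearson correlation from its definition and
    accumulates Fisher-z values per voxel, splitting by Euclidean distance
    (ties to short range).
    """
    values = np.asarray(values, dtype=float)
    coords = np.asarray(coords_mm, dtype=float)
    V, T = values.shape
    long_v = np.zeros(V)
    short_v = np.zeros(V)
    global_v = np.zeros(V)
    clip = 1.0 - 1e-7
    for i in range(V):
        xi = values[i] - values[i].mean()
        for j in range(V):
            if i == j:
                continue
            xj = values[j] - values[j].mean()
            r = float(xi @ xj / np.sqrt((xi @ xi) * (xj @ xj)))
            if r > r_threshold:
                z = float(np.arctanh(min(max(r, -clip), clip)))
                d = float(np.linalg.norm(coords[i] - coords[j]))
                global_v[i] += z
                if d > cutoff_mm:
                    long_v[i] += z
                else:
                    short_v[i] += z
    return long_v, short_v, global_v


def random_timeseries(rng, n_voxels, n_time, spread_mm=60.0):
    """Random VoxelTimeSeries on a synthetic grid with scattered coords."""
    side = int(np.ceil(n_voxels ** (1 / 3))) + 2
    grid = (side, side, side)
    idx = rng.choice(side ** 3, size=n_voxels, replace=False)
    affine = np.eye(4)
    vox = spread_mm / side
    affine[0, 0] = affine[1, 1] = affine[2, 2] = vox
    values = rng.standard_normal((n_voxels, n_time))
    # plant some correlated pairs so thresholds actually bite
    for _ in range(max(1, n_voxels // 5)):
        i, j = rng.choice(n_voxels, size=2, replace=False)
        lam = rng.uniform(0.3, 0.9)
        values[j] = lam * values[i] + (1 - lam) * values[j]
    from rsfcs.containers import VoxelTimeSeries, voxel_coords_mm
    coords = voxel_coords_mm(idx, grid, affine)
    return VoxelTimeSeries(values=values, coords_mm=coords, voxel_index=idx,
                           grid_shape=grid, affine=affine)


@pytest.fixture(scope="session")
def null_cohort():
    """Desk-scale two-group phantom without any planted effect."""
    return rsfcs.make_phantom_cohort(rsfcs.desk_cohort(seed=11))


@pytest.fixture(scope="session")
def effect_cohort():
    """Desk-scale phantom with the planted long-range hub reduction."""
    return rsfcs.make_phantom_cohort(rsfcs.desk_cohort(seed=7, delta_r=0.5))


@pytest.fixture(scope="session")
def preprocessed_ts(null_cohort):
    """Fully preprocessed gray-matter time series of one subject."""
    c = null_cohort
    ts, verdict = preprocess_subject(c.subjects[0], c.motion[0], c.gm_mask,
                                     c.wm_mask, c.csf_mask, AnalysisParams())
    assert verdict.included
    return ts
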