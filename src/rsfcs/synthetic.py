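"""Two-group 4D BOLD phantoms with known voxel-correlation structure.

The generator plants a block-structured correlation network inside a
gray-matter region: each block shares a latent signal, blocks are mutually
correlated through a block-level correlation matrix, and background voxels
carry independent noise.  A group effect is planted by multiplicatively
reducing the hub block's between-block correlations in the patient group,
emulating a focal loss of long-range connectivity strength.  Optionally a
clinical variable (HbA1c) is coupled to the hub's connectivity so that
correlation-recovery of brain-behaviour associations can be tested against
ground truth.

Signal model for a voxel in block ``b``::

    y_i(t) = sqrt(w) * s_b(t) + sqrt(1 - w) * e_i(t),   w = target_r_within

so within-block voxel correlation is ``w`` and between-block voxel
correlation is ``w * B[b, c]`` where ``B`` is the block-level (latent)
correlation matrix.  ``B`` off-diagonals are set to
``target_r_between / target_r_within`` so voxel pairs across blocks hit
``target_r_between`` exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .containers import BoldImage

__all__ = [
    "NetworkSpec",
    "EffectSpec",
    "CohortSpec",
    "Cohort",
    "GroundTruth",
    "correlated_timeseries",
    "make_motion_trace",
    "make_phantom_cohort",
    "desk_network",
    "desk_cohort",
]

BOLD_BASELINE = 1000.0
#: per-subject between-block modulation strength used for clinical coupling
COUPLING_GAMMA = 0.45
#: end-to-end shrinkage of the planted clinical coupling: the product of the
#: (latent modulator -> realized ROI FCS) attenuation (0.787, measured over
#: 720 simulated patients) and the clipped-modulator variance loss on the
#: HbA1c side.  The HbA1c mixing weight divides the requested target
#: correlation by this factor so the realized ROI-level partial correlation
#: lands on the target.  Calibrated once by simulation.
COUPLING_ATTENUATION = 0.74

# Table-style cohort marginals used for the clinical table (age in years,
# education in years, HbA1c in %, FBG in mmol/L, TMT-A in seconds)
_CLINICAL_MARGINALS = {
    "control": dict(age=(55.2, 7.0), education=(10.9, 2.7), hba1c=(5.6, 0.35),
                    fbg=(5.1, 0.67), mmse=(29.4, 1.0), tmt_a=(59.0, 28.5)),
    "patient": dict(age=(56.2, 7.7), education=(11.4, 3.2), hba1c=(8.6, 2.05),
                    fbg=(8.3, 2.70), mmse=(29.1, 1.0), tmt_a=(62.7, 27.2)),
}


def correlated_timeseries(corr_matrix: np.ndarray, n_timepoints: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Gaussian node-by-time matrix with a prescribed correlation matrix.

    The target correlation is induced by applying the Cholesky factor of
    ``corr_matrix`` to independent standard-normal innovations; rows are
    then sample-standardized (zero mean, unit variance), which leaves the
    expected sample correlation equal to the target.

    Raises
    ------
    ValueError
        If the matrix is not symmetric with unit diagonal, or not positive
        definite (the message names the smallest eigenvalue).
    """
    C = np.asarray(corr_matrix, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("corr_matrix must be square")
    if not np.allclose(C, C.T, atol=1e-10):
        raise ValueError("corr_matrix must be symmetric")
    if not np.allclose(np.diag(C), 1.0, atol=1e-10):
        raise ValueError("corr_matrix must have unit diagonal")
    eigvals = np.linalg.eigvalsh(C)
    if eigvals[0] <= 0:
        raise ValueError(
            f"corr_matrix is not positive definite (smallest eigenvalue {eigvals[0]:.6g})"
        )
    L = np.linalg.cholesky(C)
    X = L @ rng.standard_normal((C.shape[0], n_timepoints))
    X -= X.mean(axis=1, keepdims=True)
    X /= X.std(axis=1, keepdims=True)
    return X


def make_motion_trace(n_timepoints: int, amplitude_mm: float = 0.3,
                      amplitude_deg: float = 0.3,
                      rng: np.random.Generator | None = None,
                      spike: tuple[int, int, float] | None = None) -> np.ndarray:
    """Smooth random-walk head-motion trace, 6 columns.

    Columns 0-2 are translations (mm), 3-5 rotations (degrees).  The walk is
    scaled so the peak absolute excursion of each column equals its
    amplitude.  ``spike=(t, axis, size)`` overwrites one sample with exactly
    ``size``, for planting quality-control violations.
    """
    if amplitude_mm < 0 or amplitude_deg < 0:
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    walk = np.cumsum(rng.standard_normal((n_timepoints, 6)), axis=0)
    walk = gaussian_filter1d(walk, sigma=3.0, axis=0, mode="nearest")
    peak = np.abs(walk).max(axis=0)
    peak[peak == 0] = 1.0
    amps = np.array([amplitude_mm] * 3 + [amplitude_deg] * 3)
    trace = walk / peak * amps
    if spike is not None:
        t, axis, size = spike
        trace[t, axis] = size
    return trace


@dataclass
class NetworkSpec:
    """Spatial layout and correlation targets of the planted network.

    ``blocks`` maps a block name to an ``(k, 3)`` array of voxel indices;
    blocks must be disjoint and lie inside the gray-matter mask.
    """

    gm_prob: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    blocks: dict[str, np.ndarray]
    target_r_within: float = 0.5
    target_r_between: float = 0.3
    gm_threshold: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.target_r_within < 1):
            raise ValueError("target_r_within must be in (0, 1)")
        if not (0 <= self.target_r_between < self.target_r_within):
            raise ValueError("target_r_between must be in [0, target_r_within)")
        seen: set[tuple[int, int, int]] = set()
        gm = self.gm_mask
        for name, idx in self.blocks.items():
            idx = np.asarray(idx)
            if idx.ndim != 2 or idx.shape[1] != 3:
                raise ValueError(f"block {name!r} must be (k, 3) voxel indices")
            for v in map(tuple, idx):
                if v in seen:
                    raise ValueError(f"blocks overlap at voxel {v}")
                seen.add(v)
                if not gm[v]:
                    raise ValueError(f"block {name!r} voxel {v} outside gray-matter mask")

    @property
    def gm_mask(self) -> np.ndarray:
        return self.gm_prob > self.gm_threshold

    def node_correlation(self) -> np.ndarray:
        """Block-level latent correlation matrix implied by the targets."""
        n = len(self.blocks)
        off = self.target_r_between / self.target_r_within
        B = np.full((n, n), off)
        np.fill_diagonal(B, 1.0)
        return B


@dataclass
class EffectSpec:
    """Planted group difference: the hub block's between-block correlations
    are multiplied by ``1 - delta_r`` in the patient group.

    ``affected_range`` declares whether the reduced partner blocks lie
    beyond (``"long"``), within (``"short"``) or on either side
    (``"both"``) of the analysis distance cutoff; the generator validates
    the geometry against this claim.  ``hba1c_partial_r`` (e.g. ``-0.4``)
    couples patients' HbA1c to their hub connectivity for
    correlation-recovery experiments; 0 disables the coupling.
    """

    hub_block: str = "hub"
    delta_r: float = 0.0
    affected_range: str = "long"
    hba1c_partial_r: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_r <= 1.0):
            raise ValueError("delta_r must be in [0, 1]")
        if self.affected_range not in ("long", "short", "both"):
            raise ValueError("affected_range must be 'long', 'short' or 'both'")
        if not (-1.0 < self.hba1c_partial_r < 1.0):
            raise ValueError("hba1c_partial_r must be in (-1, 1)")


@dataclass
class CohortSpec:
    """Full description of a synthetic two-group cohort.

    ``n_per_group`` is ``(n_controls, n_patients)``; the patient group
    carries the planted effect.  ``distance_cutoff_mm`` is the long/short
    partition boundary the downstream analysis will use — the generator
    validates the hub/partner geometry against it.
    """

    network: NetworkSpec
    effect: EffectSpec = field(default_factory=EffectSpec)
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 180
    tr_seconds: float = 2.0
    n_per_group: tuple[int, int] = (8, 8)
    noise_sd: float = 1.0
    distance_cutoff_mm: float = 18.0
    motion_amplitude_mm: float = 0.3
    motion_amplitude_deg: float = 0.3
    temporal_smoothing_sigma: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes of at least 4 voxels")
        if self.n_timepoints <= 20:
            raise ValueError("n_timepoints must exceed 20")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if min(self.n_per_group) < 1:
            raise ValueError("both groups need at least one subject")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def affine(self) -> np.ndarray:
        """Voxel-to-mm affine centering the grid at the origin."""
        A = np.eye(4)
        A[0, 0] = A[1, 1] = A[2, 2] = self.voxel_size_mm
        A[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return A


@dataclass
class GroundTruth:
    """Planted structure: integer block label map (0 = background) and a
    boolean map of the voxels whose long/short-range FCS the effect alters
    (hub plus all reduced partner blocks when ``delta_r > 0``)."""

    block_map: np.ndarray
    effect_map: np.ndarray
    block_names: list[str]
    hub_block: str


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[BoldImage]
    motion: list[np.ndarray]
    clinical: pd.DataFrame
    gm_prob: np.ndarray
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    csf_mask: np.ndarray
    ground_truth: GroundTruth
    affine: np.ndarray
    #: per-subject latent hub-connectivity modulator (patients; NaN controls)
    hub_modulator: np.ndarray = field(default=None)  # type: ignore[assignment]


def _block_pair_distances(spec: CohortSpec, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    A = np.asarray(a, float) * spec.voxel_size_mm
    B = np.asarray(b, float) * spec.voxel_size_mm
    d = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    return d.ravel()


def _validate_effect_geometry(spec: CohortSpec) -> None:
    """Check that reduced hub-partner voxel pairs lie on the claimed side of
    the distance cutoff."""
    eff, net = spec.effect, spec.network
    if eff.hub_block not in net.blocks:
        raise ValueError(f"hub block {eff.hub_block!r} not in network")
    if eff.delta_r == 0 or eff.affected_range == "both":
        return
    hub = net.blocks[eff.hub_block]
    for name, idx in net.blocks.items():
        if name == eff.hub_block:
            continue
        d = _block_pair_distances(spec, hub, idx)
        if eff.affected_range == "long" and not np.all(d > spec.distance_cutoff_mm):
            raise ValueError(
                f"affected_range='long' but some hub-{name} pairs are within "
                f"{spec.distance_cutoff_mm} mm (min {d.min():.1f} mm)")
        if eff.affected_range == "short" and not np.all(d < spec.distance_cutoff_mm):
            raise ValueError(
                f"affected_range='short' but some hub-{name} pairs are beyond "
                f"{spec.distance_cutoff_mm} mm (max {d.max():.1f} mm)")


def _subject_node_corr(spec: CohortSpec, group: str, modulator: float) -> np.ndarray:
    """Block-level correlation matrix for one subject."""
    net, eff = spec.network, spec.effect
    B = net.node_correlation()
    names = list(net.blocks)
    h = names.index(eff.hub_block) if eff.hub_block in names else -1
    if h >= 0:
        scale = 1.0
        if group == "patient" and eff.delta_r > 0:
            scale *= 1.0 - eff.delta_r
        if group == "patient" and eff.hba1c_partial_r != 0.0:
            scale *= 1.0 + COUPLING_GAMMA * modulator
        if scale != 1.0:
            # keep the modulated row inside the positive-definite region
            row = np.clip(B[h] * scale, -0.95, 0.95)
            row[h] = 1.0
            B[h, :] = row
            B[:, h] = row
    eigmin = np.linalg.eigvalsh(B)[0]
    if eigmin <= 0:
        raise ValueError(
            f"planted effect breaks positive definiteness (smallest eigenvalue {eigmin:.3g})")
    return B


def _simulate_subject(spec: CohortSpec, group: str, modulator: float,
                      rng: np.random.Generator, subject_id: str) -> BoldImage:
    net = spec.network
    T = spec.n_timepoints
    shape = spec.grid_shape
    w = net.target_r_within
    B = _subject_node_corr(spec, group, modulator)
    latents = correlated_timeseries(B, T, rng)

    data = np.zeros(shape + (T,), dtype=np.float32)
    gm = net.gm_mask
    block_voxels = np.zeros(shape, dtype=bool)
    for k, (name, idx) in enumerate(net.blocks.items()):
        idx = np.asarray(idx)
        eps = rng.standard_normal((len(idx), T))
        y = np.sqrt(w) * latents[k] + np.sqrt(1.0 - w) * eps
        data[idx[:, 0], idx[:, 1], idx[:, 2], :] = y
        block_voxels[idx[:, 0], idx[:, 1], idx[:, 2]] = True

    background = gm & ~block_voxels
    data[background] = spec.noise_sd * rng.standard_normal((background.sum(), T))
    data[net.wm_mask] = spec.noise_sd * rng.standard_normal((net.wm_mask.sum(), T))
    data[net.csf_mask] = spec.noise_sd * rng.standard_normal((net.csf_mask.sum(), T))

    if spec.temporal_smoothing_sigma > 0:
        brain = gm | net.wm_mask | net.csf_mask
        data[brain] = gaussian_filter1d(
            data[brain], sigma=spec.temporal_smoothing_sigma, axis=-1, mode="nearest")

    data[gm | net.wm_mask | net.csf_mask] += BOLD_BASELINE
    return BoldImage(data=data, affine=spec.affine(), tr_seconds=spec.tr_seconds,
                     subject_id=subject_id)


def _clinical_row(rng: np.random.Generator, group: str, modulator: float,
                  coupling: float) -> dict:
    m = _CLINICAL_MARGINALS[group]
    row = {}
    for var in ("age", "education", "fbg", "mmse", "tmt_a"):
        mu, sd = m[var]
        row[var] = mu + sd * rng.standard_normal()
    mu, sd = m["hba1c"]
    if group == "patient" and coupling != 0.0:
        a = min(0.99, abs(coupling) / COUPLING_ATTENUATION)
        sign = -1.0 if coupling < 0 else 1.0
        row["hba1c"] = mu + sd * (sign * a * modulator
                                  + np.sqrt(1 - a ** 2) * rng.standard_normal())
    else:
        row["hba1c"] = mu + sd * rng.standard_normal()
    row["age"] = float(np.clip(row["age"], 30, 80))
    row["education"] = float(np.clip(row["education"], 3, 20))
    row["hba1c"] = float(np.clip(row["hba1c"], 4.0, 16.0))
    row["fbg"] = float(np.clip(row["fbg"], 3.0, 18.0))
    row["mmse"] = float(np.clip(round(row["mmse"]), 27, 30))
    row["tmt_a"] = float(np.clip(row["tmt_a"], 15, 180))
    return row


def make_phantom_cohort(spec: CohortSpec) -> Cohort:
    """Generate the full two-group cohort described by ``spec``.

    Deterministic given ``spec.rng_seed``.  Returns per-subject 4D images
    and motion traces, tissue masks, a clinical table and the planted
    ground truth.
    """
    _validate_effect_geometry(spec)
    rng = np.random.default_rng(spec.rng_seed)
    net = spec.network

    subjects: list[BoldImage] = []
    motion: list[np.ndarray] = []
    rows: list[dict] = []
    modulators: list[float] = []
    n_ctrl, n_pat = spec.n_per_group
    genders = ["M", "F"]
    for g, (group, n) in enumerate((("control", n_ctrl), ("patient", n_pat))):
        for i in range(n):
            sid = f"{'ctrl' if group == 'control' else 'pat'}{i:03d}"
            if group == "patient" and spec.effect.hba1c_partial_r != 0.0:
                u = float(np.clip(rng.standard_normal(), -1.8, 1.8))
            else:
                u = float("nan") if group == "control" else 0.0
            img = _simulate_subject(spec, group, 0.0 if np.isnan(u) else u, rng, sid)
            trace = make_motion_trace(spec.n_timepoints, spec.motion_amplitude_mm,
                                      spec.motion_amplitude_deg, rng)
            row = _clinical_row(rng, group, 0.0 if np.isnan(u) else u,
                                spec.effect.hba1c_partial_r)
            row.update(subject=sid, group=group, gender=genders[i % 2])
            subjects.append(img)
            motion.append(trace)
            rows.append(row)
            modulators.append(u)

    clinical = pd.DataFrame(rows)[
        ["subject", "group", "age", "gender", "education",
         "hba1c", "fbg", "mmse", "tmt_a"]]

    block_map = np.zeros(spec.grid_shape, dtype=np.int16)
    names = list(net.blocks)
    for k, name in enumerate(names, start=1):
        idx = np.asarray(net.blocks[name])
        block_map[idx[:, 0], idx[:, 1], idx[:, 2]] = k
    effect_map = np.zeros(spec.grid_shape, dtype=bool)
    if spec.effect.delta_r > 0 or spec.effect.hba1c_partial_r != 0.0:
        effect_map = block_map > 0  # hub and every reduced partner block
    gt = GroundTruth(block_map=block_map, effect_map=effect_map,
                     block_names=names, hub_block=spec.effect.hub_block)

    return Cohort(spec=spec, subjects=subjects, motion=motion, clinical=clinical,
                  gm_prob=net.gm_prob, gm_mask=net.gm_mask, wm_mask=net.wm_mask,
                  csf_mask=net.csf_mask, ground_truth=gt, affine=spec.affine(),
                  hub_modulator=np.array(modulators))


# ---------------------------------------------------------------------------
# Desk-scale default geometry
# ---------------------------------------------------------------------------

def _box(x: slice, y: slice, z: slice) -> np.ndarray:
    gx, gy, gz = np.meshgrid(np.arange(x.start, x.stop),
                             np.arange(y.start, y.stop),
                             np.arange(z.start, z.stop), indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def desk_network(grid_shape: tuple[int, int, int] = (12, 12, 12),
                 target_r_within: float = 0.5,
                 target_r_between: float = 0.42,
                 affected_range: str = "long") -> NetworkSpec:
    """Default desk-scale network on a 12-cubed grid.

    Gray matter is the interior 10-cubed box.  A hub block sits against one
    face; two partner blocks sit either against the opposite face (every
    hub-partner voxel pair more than 18 mm apart at 3 mm voxels, i.e. a
    purely long-range connection under the desk-scale cutoff) or adjacent
    to the hub (purely short-range) depending on ``affected_range``.
    Small white-matter and CSF patches sit in the border shell for the
    nuisance-signal regressors.
    """
    if any(s < 12 for s in grid_shape):
        raise ValueError("desk network needs a grid of at least 12 voxels per axis")
    gm_prob = np.full(grid_shape, 0.05)
    gm_prob[1:11, 1:11, 1:11] = 0.9

    wm_mask = np.zeros(grid_shape, dtype=bool)
    wm_mask[0, 4:8, 4:8] = True
    csf_mask = np.zeros(grid_shape, dtype=bool)
    csf_mask[11, 4:8, 4:8] = True

    hub = _box(slice(1, 3), slice(4, 8), slice(4, 8))          # 2 x 4 x 4
    if affected_range == "long":
        p1 = _box(slice(9, 11), slice(1, 5), slice(4, 8))      # >= 7 voxels away in x
        p2 = _box(slice(9, 11), slice(6, 10), slice(4, 8))
    elif affected_range == "short":
        p1 = _box(slice(4, 6), slice(1, 5), slice(4, 8))       # adjacent to hub
        p2 = _box(slice(4, 6), slice(6, 10), slice(4, 8))
    else:
        raise ValueError("desk_network supports affected_range 'long' or 'short'")
    blocks = {"hub": hub, "partner1": p1, "partner2": p2}
    return NetworkSpec(gm_prob=gm_prob, wm_mask=wm_mask, csf_mask=csf_mask,
                       blocks=blocks, target_r_within=target_r_within,
                       target_r_between=target_r_between)


def desk_cohort(n_per_group: tuple[int, int] = (8, 8), delta_r: float = 0.0,
                affected_range: str = "long", hba1c_partial_r: float = 0.0,
                seed: int = 0, **overrides) -> CohortSpec:
    """Desk-scale cohort spec: 12-cubed 3 mm grid, 180 volumes at TR 2 s,
    8 + 8 subjects, long/short partition at 18 mm (the 75 mm full-scale
    cutoff scaled to the phantom's spatial extent)."""
    network = overrides.pop("network", None)
    if network is None:
        network = desk_network(affected_range=affected_range)
    effect = EffectSpec(delta_r=delta_r, affected_range=affected_range,
                        hba1c_partial_r=hba1c_partial_r)
    return CohortSpec(network=network, effect=effect, n_per_group=n_per_group,
                      rng_seed=seed, **overrides)
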