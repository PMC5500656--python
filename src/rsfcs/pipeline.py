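"""End-to-end orchestration.

Stage order: simulate-or-ingest -> subject preprocessing (volume discard,
motion QC, nuisance regression, band-pass) -> FCS maps per correlation
threshold -> smoothing -> group inference on long- and short-range FCS ->
seeds at significant peaks -> seed FC maps -> group inference on seed FC ->
ROI/clinical statistics.

Two entry points: :func:`analyze_cohort` runs everything in memory on a
:class:`~rsfcs.synthetic.Cohort` (what the test-bench and simulation
studies use), and :func:`run_pipeline` wraps it with disk I/O and a run
manifest for the command-line interface.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .containers import BoldImage, VoxelTimeSeries, extract_timeseries
from .fcs import FcsMaps, fcs_maps, smooth_fcs
from .inference import (MapStack, TMap, alphasim_min_extent, alphasim_null,
                        build_design, estimate_smoothness, extract_clusters,
                        fit_voxel_glm)
from .preprocess import (QcVerdict, bandpass, build_confounds,
                         discard_initial_volumes, motion_qc, regress_nuisance)
from .seed import SeedSpec, seed_fc_map, sphere_voxels
from .stats import correlation_battery, demographics_tests, roi_mean
from .synthetic import Cohort, CohortSpec, make_phantom_cohort

__all__ = ["AnalysisParams", "PipelineResult", "preprocess_subject",
           "analyze_cohort", "run_pipeline", "RunConfig"]


@dataclass
class AnalysisParams:
    """Analysis options; every default is the standard full-scale constant
    (10 discarded volumes, 2 mm / 2 deg QC limits, 0.01-0.08 Hz band,
    r > 0.2 with a 0.1/0.3 robustness sweep, 75 mm long/short cutoff,
    6 mm FWHM smoothing, voxel p = 0.001 with 1000 Monte-Carlo simulations
    at cluster alpha = 0.05, 18-connectivity)."""

    n_discard: int = 10
    trans_limit_mm: float = 2.0
    rot_limit_deg: float = 2.0
    low_hz: float = 0.01
    high_hz: float = 0.08
    r_threshold: float = 0.2
    sweep_thresholds: tuple[float, ...] = (0.1, 0.2, 0.3)
    cutoff_mm: float | None = None          # None -> cohort spec value, else 75
    fwhm_mm: float = 6.0
    voxel_p: float = 0.001
    n_sims: int = 1000
    alpha: float = 0.05
    connectivity: int = 18
    covariates: tuple[str, ...] = ("age", "gender", "education")
    stat_targets: tuple[str, ...] = ("hba1c", "fbg", "mmse", "tmt_a")
    seed_diameter_mm: float = 6.0
    rng_seed: int = 0

    def resolve_cutoff(self, cohort: Cohort | None) -> float:
        if self.cutoff_mm is not None:
            return self.cutoff_mm
        if cohort is not None:
            return cohort.spec.distance_cutoff_mm
        return 75.0


@dataclass
class RangeInference:
    tmap: TMap
    fwhm_mm: np.ndarray
    min_extent: int
    clusters: pd.DataFrame
    null_max_extents: np.ndarray


@dataclass
class PipelineResult:
    qc: list[QcVerdict]
    included: np.ndarray                    # boolean per input subject
    clinical: pd.DataFrame                  # included subjects only
    fcs_stacks: dict[str, MapStack]         # 'long'/'short'/'global', smoothed
    inference: dict[str, RangeInference]    # per range
    seeds: list[SeedSpec]
    seed_inference: dict[str, RangeInference]
    roi_tables: dict[str, pd.DataFrame]
    demographics: pd.DataFrame
    counters: dict[str, int]
    params: AnalysisParams


def preprocess_subject(img: BoldImage, trace: np.ndarray, gm_mask: np.ndarray,
                       wm_mask: np.ndarray, csf_mask: np.ndarray,
                       params: AnalysisParams
                       ) -> tuple[VoxelTimeSeries | None, QcVerdict]:
    """Full subject-level temporal pipeline; returns None when QC excludes
    the subject."""
    img = discard_initial_volumes(img, params.n_discard)
    trace = np.asarray(trace)[params.n_discard:]
    verdict = motion_qc(trace, params.trans_limit_mm, params.rot_limit_deg,
                        subject_id=img.subject_id)
    if not verdict.included:
        return None, verdict
    ts = extract_timeseries(img, gm_mask, mask_source="gray-matter")
    confounds = build_confounds(trace, img, wm_mask, csf_mask)
    ts = regress_nuisance(ts, confounds)
    ts = bandpass(ts, img.tr_seconds, params.low_hz, params.high_hz)
    return ts, verdict


def _infer_on_stack(stack: MapStack, design, params: AnalysisParams,
                    voxel_size_mm: float, rng: np.random.Generator
                    ) -> RangeInference:
    tmap, resid = fit_voxel_glm(stack, design)
    fwhm = estimate_smoothness(resid, stack.mask_array(), voxel_size_mm)
    null = alphasim_null(stack.mask_array(), fwhm, voxel_size_mm,
                         voxel_p=params.voxel_p, n_sims=params.n_sims,
                         connectivity=params.connectivity, rng=rng)
    k = alphasim_min_extent(stack.mask_array(), fwhm, voxel_size_mm,
                            voxel_p=params.voxel_p, alpha=params.alpha,
                            null_max_extents=null)
    clusters = extract_clusters(tmap, params.voxel_p, k,
                                connectivity=params.connectivity,
                                null_max_extents=null)
    return RangeInference(tmap=tmap, fwhm_mm=fwhm, min_extent=k,
                          clusters=clusters, null_max_extents=null)


def analyze_cohort(cohort: Cohort, params: AnalysisParams | None = None,
                   ranges: tuple[str, ...] = ("long", "short"),
                   do_seed_fc: bool = True, do_roistats: bool = True
                   ) -> PipelineResult:
    """Run the full analysis on an in-memory cohort."""
    params = params or AnalysisParams()
    cutoff = params.resolve_cutoff(cohort)
    voxel = cohort.spec.voxel_size_mm

    series: list[VoxelTimeSeries] = []
    verdicts: list[QcVerdict] = []
    included = []
    per_subject_fcs: list[FcsMaps] = []
    counters = {"n_clipped": 0, "n_distance_ties": 0}
    distances = None
    for img, trace in zip(cohort.subjects, cohort.motion):
        ts, verdict = preprocess_subject(img, trace, cohort.gm_mask,
                                         cohort.wm_mask, cohort.csf_mask, params)
        verdicts.append(verdict)
        included.append(ts is not None)
        if ts is None:
            continue
        if distances is None:
            from scipy.spatial.distance import pdist, squareform
            distances = squareform(pdist(ts.coords_mm))
        maps = fcs_maps(ts, r_threshold=params.r_threshold, cutoff_mm=cutoff,
                        distances=distances)
        counters["n_clipped"] += maps.n_clipped
        counters["n_distance_ties"] = maps.n_distance_ties
        per_subject_fcs.append(smooth_fcs(maps, params.fwhm_mm, voxel))
        series.append(ts)

    included = np.asarray(included, dtype=bool)
    if included.sum() < len(params.covariates) + 4:
        raise RuntimeError("too few subjects survive motion QC for inference")
    clinical = cohort.clinical.loc[included].reset_index(drop=True)
    design = build_design(clinical, covariates=params.covariates)

    fcs_stacks = {
        which: MapStack.from_maps([m.map_for(which) for m in per_subject_fcs],
                                  cohort.gm_mask, cohort.affine)
        for which in ("long", "short", "global")
    }

    rng = np.random.default_rng(params.rng_seed)
    inference = {r: _infer_on_stack(fcs_stacks[r], design, params, voxel, rng)
                 for r in ranges}

    # --- seed-based follow-up at significant peaks -------------------------
    seeds: list[SeedSpec] = []
    seed_inference: dict[str, RangeInference] = {}
    roi_tables: dict[str, pd.DataFrame] = {}
    if do_seed_fc:
        for r in ranges:
            cl = inference[r].clusters
            for i, row in cl.iterrows():
                seeds.append(SeedSpec(
                    center_mm=[row.peak_x_mm, row.peak_y_mm, row.peak_z_mm],
                    diameter_mm=params.seed_diameter_mm,
                    label=f"{r}_cluster{i}"))
        for seed_spec in seeds:
            vox = sphere_voxels(seed_spec, series[0])
            zmaps = []
            for ts in series:
                zmap, _ = seed_fc_map(ts, vox)
                from .fcs import smooth_map
                zmaps.append(smooth_map(zmap, params.fwhm_mm, voxel))
            stack = MapStack.from_maps(zmaps, cohort.gm_mask, cohort.affine)
            seed_inference[seed_spec.label] = _infer_on_stack(
                stack, design, params, voxel, rng)

    # --- ROI-level clinical statistics ------------------------------------
    demographics = demographics_tests(clinical)
    if do_roistats:
        roi_cols: dict[str, np.ndarray] = {}
        grid = cohort.gm_mask.shape
        for r in ranges:
            cl = inference[r].clusters
            tmap = inference[r].tmap
            from scipy import ndimage, stats as sps
            tcrit = sps.t.ppf(1 - params.voxel_p / 2, tmap.df)
            from .inference import _structure
            for sign_name, signed in (("increase", tmap.t), ("decrease", -tmap.t)):
                supra = (signed >= tcrit) & tmap.mask
                labels, n = ndimage.label(supra, structure=_structure(params.connectivity))
                for lab in range(1, n + 1):
                    comp = labels == lab
                    if comp.sum() < inference[r].min_extent:
                        continue
                    name = f"{r}_{sign_name}_{lab}"
                    vals = np.array([roi_mean(m.map_for(r), comp)
                                     for m in per_subject_fcs])
                    roi_cols[name] = vals
        min_group = clinical.groupby("group").size().min()
        if roi_cols and min_group >= len(params.covariates) + 4:
            roi_values = pd.DataFrame(roi_cols, index=clinical["subject"])
            targets = [t for t in params.stat_targets if t in clinical.columns]
            tidy, comparison = correlation_battery(
                roi_values, clinical, targets, covariates=params.covariates)
            roi_tables["partial_correlations"] = tidy
            roi_tables["group_comparison"] = comparison

    return PipelineResult(qc=verdicts, included=included, clinical=clinical,
                          fcs_stacks=fcs_stacks, inference=inference,
                          seeds=seeds, seed_inference=seed_inference,
                          roi_tables=roi_tables, demographics=demographics,
                          counters=counters, params=params)


# ---------------------------------------------------------------------------
# Disk-backed run
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Configuration of a full disk-backed run.

    Either ``simulate`` holds a cohort spec (phantom study) or ``input_dir``
    points at per-subject NIfTI + motion text + clinical CSV laid out as
    written by ``rsfcs simulate``.
    """

    out_dir: str
    simulate: CohortSpec | None = None
    input_dir: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of simulate/input_dir must be given")


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write a cohort to disk: per-subject 4D NIfTI + motion text, tissue
    masks, clinical CSV, ground-truth label map and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for img, trace in zip(cohort.subjects, cohort.motion):
        p = rio.write_bold(out / f"{img.subject_id}_bold.nii.gz", img)
        files[f"bold:{img.subject_id}"] = str(p)
        p = rio.write_motion_trace(out / f"{img.subject_id}_motion.txt", trace)
        files[f"motion:{img.subject_id}"] = str(p)
    rio.write_nifti(out / "gm_prob.nii.gz", cohort.gm_prob, cohort.affine)
    rio.write_nifti(out / "wm_mask.nii.gz", cohort.wm_mask.astype(np.uint8), cohort.affine)
    rio.write_nifti(out / "csf_mask.nii.gz", cohort.csf_mask.astype(np.uint8), cohort.affine)
    rio.write_nifti(out / "ground_truth_blocks.nii.gz",
                    cohort.ground_truth.block_map, cohort.affine)
    rio.write_table(out / "clinical.csv", cohort.clinical)
    spec = cohort.spec
    manifest = {
        "grid_shape": list(spec.grid_shape), "voxel_size_mm": spec.voxel_size_mm,
        "n_timepoints": spec.n_timepoints, "tr_seconds": spec.tr_seconds,
        "n_per_group": list(spec.n_per_group), "noise_sd": spec.noise_sd,
        "distance_cutoff_mm": spec.distance_cutoff_mm, "rng_seed": spec.rng_seed,
        "delta_r": spec.effect.delta_r, "affected_range": spec.effect.affected_range,
        "hub_block": spec.effect.hub_block,
        "block_names": cohort.ground_truth.block_names,
        "subjects": [s.subject_id for s in cohort.subjects],
    }
    rio.write_json(out / "cohort_manifest.json", manifest)
    return manifest


def run_pipeline(config: RunConfig) -> dict:
    """Run the pipeline per config and write all stage outputs plus a run
    manifest (config echo, per-stage timings, output hashes, QC exclusions,
    counters and Monte-Carlo seed)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.simulate is not None:
        cohort = make_phantom_cohort(config.simulate)
        write_cohort(cohort, out / "cohort")
    else:
        cohort = load_cohort(config.input_dir)
    timings["simulate_or_ingest"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    result = analyze_cohort(cohort, config.params)
    timings["analysis"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    outputs: dict[str, str] = {}
    qc_df = pd.DataFrame([{
        "subject": v.subject_id,
        **{f"max_trans_{a}_mm": v.max_abs_translation_mm[i] for i, a in enumerate("xyz")},
        **{f"max_rot_{a}_deg": v.max_abs_rotation_deg[i] for i, a in enumerate("xyz")},
        "included": v.included} for v in result.qc])
    outputs["qc"] = str(rio.write_table(out / "qc_verdicts.csv", qc_df))
    for r, inf in result.inference.items():
        outputs[f"tmap_{r}"] = str(rio.write_nifti(
            out / f"tmap_{r}_fcs.nii.gz", inf.tmap.t, inf.tmap.affine))
        outputs[f"clusters_{r}"] = str(rio.write_table(
            out / f"clusters_{r}_fcs.csv", inf.clusters))
    for label, inf in result.seed_inference.items():
        outputs[f"tmap_seed_{label}"] = str(rio.write_nifti(
            out / f"tmap_seed_{label}.nii.gz", inf.tmap.t, inf.tmap.affine))
        outputs[f"clusters_seed_{label}"] = str(rio.write_table(
            out / f"clusters_seed_{label}.csv", inf.clusters))
    outputs["demographics"] = str(rio.write_table(
        out / "demographics_tests.csv", result.demographics))
    for name, tab in result.roi_tables.items():
        outputs[f"roi_{name}"] = str(rio.write_table(out / f"roi_{name}.csv", tab))
    timings["write_outputs"] = time.perf_counter() - t0

    from . import __version__
    manifest = {
        "software_version": __version__,
        "params": asdict(result.params),
        "qc_excluded": [v.subject_id for v in result.qc if not v.included],
        "counters": result.counters,
        "inference": {r: {"fwhm_mm": inf.fwhm_mm.tolist(),
                          "min_extent": inf.min_extent,
                          "n_clusters": int(len(inf.clusters))}
                      for r, inf in result.inference.items()},
        "seeds": [{"label": s.label, "center_mm": s.center_mm.tolist(),
                   "diameter_mm": s.diameter_mm} for s in result.seeds],
        "timings_s": timings,
        "outputs": {k: rio.file_sha256(v) for k, v in outputs.items()},
    }
    rio.write_json(out / "run_manifest.json", manifest)
    return manifest


def load_cohort(input_dir: str | Path) -> Cohort:
    """Reload a cohort previously written by :func:`write_cohort`."""
    import json as _json
    from .synthetic import CohortSpec, EffectSpec, GroundTruth, NetworkSpec

    d = Path(input_dir)
    manifest = _json.loads((d / "cohort_manifest.json").read_text())
    gm_prob, affine = rio.read_nifti(d / "gm_prob.nii.gz")
    wm_mask, _ = rio.read_nifti(d / "wm_mask.nii.gz")
    csf_mask, _ = rio.read_nifti(d / "csf_mask.nii.gz")
    block_map, _ = rio.read_nifti(d / "ground_truth_blocks.nii.gz")
    clinical = rio.read_clinical_csv(d / "clinical.csv")

    subjects, motion = [], []
    ref_affine = None
    for sid in manifest["subjects"]:
        img = rio.read_bold(d / f"{sid}_bold.nii.gz",
                            tr_seconds=manifest["tr_seconds"], subject_id=sid)
        if ref_affine is None:
            ref_affine = img.affine
        elif not np.allclose(img.affine, ref_affine, atol=1e-4):
            raise ValueError(f"affine mismatch for subject {sid}")
        if img.grid_shape != tuple(manifest["grid_shape"]):
            raise ValueError(f"grid shape mismatch for subject {sid}")
        subjects.append(img)
        motion.append(rio.read_motion_trace(d / f"{sid}_motion.txt"))

    blocks: dict[str, np.ndarray] = {}
    for k, name in enumerate(manifest["block_names"], start=1):
        blocks[name] = np.column_stack(np.nonzero(block_map == k))
    network = NetworkSpec(gm_prob=np.asarray(gm_prob, float),
                          wm_mask=np.asarray(wm_mask, bool),
                          csf_mask=np.asarray(csf_mask, bool), blocks=blocks)
    effect = EffectSpec(hub_block=manifest["hub_block"],
                        delta_r=manifest["delta_r"],
                        affected_range=manifest["affected_range"])
    spec = CohortSpec(network=network, effect=effect,
                      grid_shape=tuple(manifest["grid_shape"]),
                      voxel_size_mm=manifest["voxel_size_mm"],
                      n_timepoints=manifest["n_timepoints"],
                      tr_seconds=manifest["tr_seconds"],
                      n_per_group=tuple(manifest["n_per_group"]),
                      noise_sd=manifest["noise_sd"],
                      distance_cutoff_mm=manifest["distance_cutoff_mm"],
                      rng_seed=manifest["rng_seed"])
    effect_map = (np.asarray(block_map) > 0) if effect.delta_r > 0 else \
        np.zeros_like(np.asarray(block_map), dtype=bool)
    gt = GroundTruth(block_map=np.asarray(block_map, dtype=np.int16),
                     effect_map=effect_map,
                     block_names=manifest["block_names"],
                     hub_block=manifest["hub_block"])
    return Cohort(spec=spec, subjects=subjects, motion=motion, clinical=clinical,
                  gm_prob=np.asarray(gm_prob, float),
                  gm_mask=np.asarray(gm_prob, float) > network.gm_threshold,
                  wm_mask=np.asarray(wm_mask, bool),
                  csf_mask=np.asarray(csf_mask, bool),
                  ground_truth=gt, affine=np.asarray(ref_affine),
                  hub_modulator=np.full(len(subjects), np.nan))
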