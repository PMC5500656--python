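"""Voxel GLM, smoothness estimation, Monte-Carlo extent threshold,
cluster extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rsfcs.fcs import smooth_map
from rsfcs.inference import (MapStack, TMap, alphasim_min_extent,
                             alphasim_null, build_design, estimate_smoothness,
                             extract_clusters, fit_voxel_glm)


def _stack(n_sub=20, shape=(6, 6, 6), seed=0):
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    maps = [rng.standard_normal(shape) for _ in range(n_sub)]
    return MapStack.from_maps(maps, mask, np.eye(4)), rng


def _design_two_group(n_sub):
    half = n_sub // 2
    clinical = pd.DataFrame({
        "group": ["control"] * half + ["patient"] * (n_sub - half)})
    return build_design(clinical, covariates=())


class TestDesign:
    def test_covariate_columns_and_contrast(self):
        rng = np.random.default_rng(0)
        clinical = pd.DataFrame({
            "group": ["control", "patient"] * 4,
            "age": rng.normal(55, 7, 8),
            "gender": ["M", "M", "F", "F"] * 2,
            "education": rng.normal(11, 3, 8)})
        d = build_design(clinical)
        assert d.names == ["intercept", "group", "age", "gender", "education"]
        assert d.contrast[1] == 1.0 and d.contrast.sum() == 1.0
        np.testing.assert_array_equal(d.X[:, 1], [0, 1] * 4)

    def test_single_group_design_is_rank_deficient(self):
        clinical = pd.DataFrame({"group": ["control"] * 8})
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(clinical, covariates=())


class TestVoxelGlm:
    def test_group_only_design_equals_pooled_t(self):
        stack, _ = _stack(24, seed=1)
        design = _design_two_group(24)
        tmap, _ = fit_voxel_glm(stack, design)
        a = stack.values[:12]
        b = stack.values[12:]
        # pooled-variance two-sample t, patient minus control direction
        t_ref = sps.ttest_ind(b, a, axis=0, equal_var=True).statistic
        np.testing.assert_allclose(tmap.t.ravel()[stack.voxel_index], t_ref,
                                   atol=1e-10)
        assert tmap.df == 22

    def test_too_few_subjects_rejected(self):
        stack, _ = _stack(3)
        with pytest.raises(ValueError, match="at least"):
            fit_voxel_glm(stack, _design_two_group(3))

    def test_planted_effect_pulls_hub_t_negative(self, effect_cohort):
        from rsfcs.pipeline import AnalysisParams, analyze_cohort
        res = analyze_cohort(effect_cohort,
                             AnalysisParams(n_sims=50, rng_seed=0),
                             do_seed_fc=False, do_roistats=False)
        tmap = res.inference["long"].tmap
        hub = effect_cohort.ground_truth.block_map == 1
        background = effect_cohort.gm_mask & (
            effect_cohort.ground_truth.block_map == 0)
        assert tmap.t[hub].mean() < tmap.t[background].mean() - 2.0

    def test_residuals_orthogonal_to_design(self):
        stack, _ = _stack(16, seed=2)
        design = _design_two_group(16)
        _, resid = fit_voxel_glm(stack, design)
        np.testing.assert_allclose(design.X.T @ resid.values, 0, atol=1e-8)


class TestSmoothness:
    def test_recovers_known_kernel_within_15_percent(self):
        rng = np.random.default_rng(3)
        shape = (20, 20, 20)
        mask = np.ones(shape, dtype=bool)
        maps = [smooth_map(rng.standard_normal(shape), 6.0, 3.0)
                for _ in range(20)]
        stack = MapStack.from_maps(maps, mask, np.eye(4))
        fwhm = estimate_smoothness(stack, mask, 3.0)
        np.testing.assert_allclose(fwhm, 6.0, rtol=0.15)

    def test_white_noise_estimate_stays_small(self):
        # unsmoothed noise has (sub-voxel) intrinsic smoothness; the
        # first-difference estimator reports well under one voxel
        stack, _ = _stack(20, shape=(12, 12, 12), seed=4)
        fwhm = estimate_smoothness(stack, stack.mask_array(), 3.0)
        assert np.all(fwhm < 3.0)
        assert np.all(fwhm >= 0.3)  # clamp floor at 0.1 voxel

    def test_constant_map_rejected(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        stack = MapStack.from_maps([np.ones((5, 5, 5))], mask, np.eye(4))
        with pytest.raises(ValueError, match="degenerate"):
            estimate_smoothness(stack, mask, 3.0)


class TestAlphaSim:
    def test_unsmoothed_noise_needs_tiny_extent(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        k = alphasim_min_extent(mask, np.zeros(3), 3.0, voxel_p=0.001,
                                n_sims=400, alpha=0.05,
                                rng=np.random.default_rng(0))
        assert k <= 3

    def test_smoothness_raises_required_extent(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        k0 = alphasim_min_extent(mask, np.zeros(3), 3.0, voxel_p=0.001,
                                 n_sims=400, rng=np.random.default_rng(1))
        k1 = alphasim_min_extent(mask, np.full(3, 12.0), 3.0, voxel_p=0.001,
                                 n_sims=400, rng=np.random.default_rng(1))
        assert k1 > k0

    def test_alpha_one_passes_everything(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        assert alphasim_min_extent(mask, np.zeros(3), 3.0, alpha=1.0,
                                   n_sims=10, rng=np.random.default_rng(2)) == 1

    def test_extent_monotone_in_alpha_and_voxel_p(self):
        mask = np.ones((12, 12, 12), dtype=bool)
        null = alphasim_null(mask, np.full(3, 6.0), 3.0, voxel_p=0.005,
                             n_sims=400, rng=np.random.default_rng(3))
        k_strict = alphasim_min_extent(mask, None, None, alpha=0.01,
                                       null_max_extents=null)
        k_loose = alphasim_min_extent(mask, None, None, alpha=0.10,
                                      null_max_extents=null)
        assert k_loose <= k_strict
        null_small_p = alphasim_null(mask, np.full(3, 6.0), 3.0, voxel_p=0.0005,
                                     n_sims=400, rng=np.random.default_rng(3))
        k_small_p = alphasim_min_extent(mask, None, None, alpha=0.05,
                                        null_max_extents=null_small_p)
        k_big_p = alphasim_min_extent(mask, None, None, alpha=0.05,
                                      null_max_extents=null)
        assert k_small_p <= k_big_p


def _toy_tmap(shape=(10, 10, 10), df=20):
    t = np.zeros(shape)
    mask = np.ones(shape, dtype=bool)
    return t, mask


class TestExtractClusters:
    def test_single_blob_reported_with_peak(self):
        t, mask = _toy_tmap()
        t[2:3, 2:4, 2:4] = 5.0      # 4 voxels
        t[2, 2, 4] = 7.0            # 5th voxel, the peak
        tmap = TMap(t=t, df=20, mask=mask, affine=np.eye(4))
        cl = extract_clusters(tmap, voxel_p=0.001, min_extent=4)
        assert len(cl) == 1
        row = cl.iloc[0]
        assert row.sign == "increase"
        assert row.extent_voxels == 5
        assert (row.peak_x_mm, row.peak_y_mm, row.peak_z_mm) == (2, 2, 4)
        assert row.peak_t == 7.0

    def test_blob_below_extent_threshold_dropped(self):
        t, mask = _toy_tmap()
        t[2:3, 2:4, 2:4] = 5.0
        t[2, 2, 4] = 7.0
        tmap = TMap(t=t, df=20, mask=mask, affine=np.eye(4))
        cl = extract_clusters(tmap, voxel_p=0.001, min_extent=6)
        assert len(cl) == 0

    def test_corner_contact_splits_under_18_connectivity(self):
        t, mask = _toy_tmap()
        t[2:4, 2:4, 2] = 6.0               # blob A (4 voxels, one slice)
        t[4:6, 4:6, 3] = 6.0               # blob B touching only at a corner
        tmap = TMap(t=t, df=20, mask=mask, affine=np.eye(4))
        cl18 = extract_clusters(tmap, voxel_p=0.001, min_extent=1,
                                connectivity=18)
        cl26 = extract_clusters(tmap, voxel_p=0.001, min_extent=1,
                                connectivity=26)
        assert len(cl18) == 2
        assert len(cl26) == 1

    def test_negative_clusters_carry_decrease_sign(self):
        t, mask = _toy_tmap()
        t[5:7, 5:7, 5:7] = -6.0
        tmap = TMap(t=t, df=20, mask=mask, affine=np.eye(4))
        cl = extract_clusters(tmap, voxel_p=0.001, min_extent=2)
        assert list(cl.sign) == ["decrease"]
        assert cl.iloc[0].peak_t < 0
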