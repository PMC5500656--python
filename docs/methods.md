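# Methods

This note documents the models, estimators and design choices behind the
package, in the order the pipeline runs them.

## Phantom generator

**Signal model.** The brain is a 3D grid (desk scale: 12³ voxels, 3 mm
isotropic) with a gray-matter probability map (mask at p > 0.3), small
white-matter and CSF patches, and a planted network of voxel *blocks*.
Each block *b* shares a latent signal `s_b(t)`; a voxel in block *b* is

    y_i(t) = sqrt(w)·s_b(t) + sqrt(1−w)·e_i(t)

with `e_i` i.i.d. Gaussian noise, so within-block voxel correlation is
`w = target_r_within` (default 0.5).  Block latents are jointly Gaussian
with correlation matrix `B`, generated by applying the Cholesky factor of
`B` to independent innovations and sample-standardizing rows; off-diagonal
entries are `target_r_between / target_r_within`, so between-block voxel
pairs hit `target_r_between` (default 0.42) exactly in expectation.
Background gray matter, WM and CSF carry independent noise (sd
`noise_sd`); a constant baseline of 1000 mimics BOLD units.  All draws
come from one seeded generator, so cohorts are bit-reproducible.
An optional order-1 temporal smoothing kernel can add BOLD-like
autocorrelation; it is off by default because all downstream metrics are
correlation-based and autocorrelation only widens nulls.

**Planted group effect.** In the patient group the hub block's row of `B`
is multiplied by `1 − delta_r`.  With `delta_r = 0.5` the hub-partner
voxel correlation drops from 0.42 to 0.21, i.e. from comfortably above to
at the 0.2 analysis threshold — a focal loss of the hub's long-range
connectivity strength.  The ground-truth effect map flags the hub and all
partner blocks (both sides of each reduced connection lose FCS).

**Geometry and the distance cutoff.** A 12³ grid at 3 mm spans ~57 mm at
most, so no voxel pair can exceed the 75 mm long/short cutoff used at
whole-brain scale.  The desk-scale cohort therefore carries its own
cutoff, 18 mm — the full-scale cutoff scaled to the phantom's extent — as
`CohortSpec.distance_cutoff_mm`; 75 mm remains the default for full-scale
analyses (`AnalysisParams.cutoff_mm`).  The default layout places the
2×4×4-voxel hub and two 2×4×4 partner blocks ≥ 7 voxels (21 mm) apart, so
every reduced connection is strictly long-range; within-block distances
(≤ 9 mm) are strictly short-range.  A "short" variant puts the partners
adjacent to the hub (all pairs < 15 mm).

**Network constants.** Block sizes and correlation targets were fixed once
at design time by pilot simulation so that the planted `delta_r = 0.5`
effect is reliably detectable at the desk scale the test bench prescribes
(8 + 8 subjects, voxel p = 0.001): weaker networks (between-block r = 0.3)
leave per-voxel effect sizes near the detection boundary at n = 16.  The
frozen defaults give pilot recovery 15/15 with mean Dice ≈ 0.6 and a null
family-wise error of ≈ 0.03.

**Clinical table.** Age, education, HbA1c, FBG, MMSE and TMT-A are drawn
from group-specific normal marginals matching a typical middle-aged
diabetes cohort (e.g. HbA1c 8.6 ± 2.05 % in patients vs 5.6 ± 0.35 % in
controls, so the group contrast is large); gender alternates for balance.
Covariates are independent of the imaging signal unless coupling is
requested.

**Clinical coupling.** For association-recovery experiments each patient
gets a latent modulator `u ~ N(0,1)` (clipped at ±1.8) scaling the hub's
between-block correlations by `1 + 0.45·u`, and HbA1c mixes `−a·u` with
independent noise.  The realized correlation between HbA1c and the
measured hub ROI FCS is attenuated by FCS measurement noise and the clip;
the mixing weight divides the requested target by a calibration constant
(0.74, measured once by simulation over 720 patients) so the realized
partial correlation lands on the requested target (pooled check over 150
cohorts: −0.400 at target −0.4).  Coupling experiments run with
`delta_r = 0.5`: the unreduced hub row (latent correlation 0.84) has no
positive-definite headroom for upward modulation, the reduced row (0.42)
does.  Modulated rows are clipped to |r| ≤ 0.95.

**What the phantom does not emulate.** No hemodynamic response, scanner
drift, physiological noise spectra, spatial autocorrelation of the noise,
susceptibility artifacts or anatomical variability.  Passing tests
demonstrate the *statistical machinery* — calibration, recovery,
exactness — under a known generative model, not performance on real scans.

## Preprocessing

Stage order is fixed: discard the first 10 volumes (of 180, leaving 170 at
TR = 2 s) → motion QC → nuisance regression → band-pass.  Whether
regression precedes filtering differs between toolchains; the fixed order
here is a documented choice.  Details:

- **QC boundary.** Exclusion requires *strictly* exceeding 2 mm / 2°
  ("larger than"); a maximum of exactly 2.0 passes.
- **Confounds.** 14 columns: 6 motion parameters, their backward-difference
  derivatives (leading zero row), mean WM and mean CSF signal.  The global
  mean signal is never a regressor.  Rank-deficient confound matrices fall
  back to the pseudo-inverse with a warning.
- **Band-pass.** Ideal rectangular DFT filter: bins with
  0.01 ≤ f ≤ 0.08 Hz kept (inclusive edges), all others — including DC —
  zeroed.  The ideal filter is idempotent, which the tests assert.  No
  detrend step is applied by default; band-passing removes linear drift's
  low-frequency content in any case.
- Regression and filtering operate on the masked gray-matter series only.

## FCS maps

Correlations are computed across all in-mask voxels (zero-variance voxels
are dropped and counted).  Policy choices, each logged in the map sidecar:

- **Threshold strictness:** `r > θ` (strict).  Since arctanh is monotone,
  thresholding on r before or after the Fisher transform selects the same
  pairs.
- **Clipping:** r is clipped to ±(1 − 1e−7) before arctanh so duplicated
  series cannot produce infinities; clip events are counted.
- **Distance ties:** pairs at exactly the cutoff (reachable on a 3 mm
  grid, e.g. offset (45, 60, 0) mm for the 75 mm cutoff) go to *short*
  range so the partition is exhaustive; ties are counted.  The partition
  identity `long + short = global` holds exactly (global is computed as
  the sum), and after smoothing the global map is recomputed as the sum of
  the smoothed parts to preserve it.
- **No normalization:** FCS is a sum, not a mean, matching the degree
  interpretation; values therefore scale with mask size.
- **Distances** use affine-transformed voxel-center coordinates.
- **Smoothing:** Gaussian, σ = FWHM/(2√(2 ln 2)) per axis in voxel units,
  zero padding outside the grid, no mask renormalization (the common SPM
  behaviour), applied after map computation (maps, not time series, are
  smoothed — smoothing the data first would manufacture local correlation).

## Seed FC

Seeds are spheres (default 6 mm diameter) at cluster peaks; membership is
inclusive at the boundary, so on a 3 mm grid a 6 mm sphere centered on a
voxel holds 7 voxels.  The seed signal is the unweighted mean of member
time series (the common convention); maps are arctanh-transformed
correlations, smoothed with the same 6 mm kernel as the FCS stream, and
computed from the same preprocessed series.

## Group inference

**GLM.** Per voxel, OLS on intercept + group (patient = 1) + age + gender
(male = 1) + education; T is the group coefficient over its standard
error, df = N − p.  Negative T means patients weaker, matching the
reporting convention for patient deficits.  With an intercept+group
design this reduces exactly to the pooled-variance two-sample t (asserted
to 1e−10).

**Smoothness.** Per-axis intrinsic FWHM from the variance of spatial first
differences of the standardized GLM residuals: for a Gaussian
autocorrelation model, neighbour correlation ρ = 1 − var(diff)/2 and
FWHM = voxel · sqrt(−2 ln 2 / ln ρ).  ρ is clamped to (1e−8, 1−1e−8) and
the estimate floored at 0.1 voxel.  Note the estimator's white-noise limit
is FWHM → 0 (sub-voxel), not one voxel; the tests assert recovery of a
known applied 6 mm kernel within 15% and the sub-voxel white-noise
behaviour.  A T-map fallback exists when residuals are unavailable.

**Cluster-extent correction.** Monte-Carlo: simulate Gaussian white noise
on the grid, smooth to the estimated FWHM, restandardize within the mask
(smoothing deflates variance; without restandardization the voxel
threshold would be miscalibrated), apply the two-sided voxel threshold
|z| ≥ Φ⁻¹(1 − p/2), and record the maximum cluster extent under the chosen
neighbourhood.  The reported minimum extent is the smallest k with
P(max extent ≥ k) ≤ α.  "Edge connected" is faces+edges, i.e.
18-connectivity (6 and 26 available).  Clusters in the observed T map are
formed at the matching two-sided t quantile for the GLM's df and extracted
per sign; cluster-level p is the empirical tail probability of the
simulated max-extent distribution.  Monte-Carlo seeds are taken from the
run's seeded generator and logged.  Full-scale studies report per-analysis
minimum extents in the tens-to-hundreds of voxels; those values depend on
real-data smoothness and are not reproducible from phantoms — the
machinery, not the constants, is what transfers.

**Null calibration.** The test bench measures the family-wise error of the
corrected long-range contrast over 100 seeded null cohorts (nominal
α = 0.05); each corrected map is one family.  The phantom's block
structure induces long-range residual correlations that a stationary
smoothness model does not capture, so calibration within [0.01, 0.10] is
the meaningful check, not exact attainment of 0.05.

## ROI and clinical statistics

- **Partial correlation:** Pearson correlation of OLS residuals after
  regressing both variables on covariates + intercept; two-sided p from
  t = r·sqrt(df/(1−r²)), df = n − 2 − k.
- **Comparison of two correlations:** Fisher z = (atanh r₁ − atanh r₂) /
  sqrt(1/(n₁−3) + 1/(n₂−3)), two-sided normal p.  Published studies
  sometimes print z values that this standard formula does not reproduce
  from their printed r and n; the standard formula is used here regardless.
- **Bonferroni family:** all ROI × variable pairs within one group's
  battery; m is printed in every report so users can re-family.
- **Demographics:** continuous variables gated by a Lilliefors-corrected
  Kolmogorov–Smirnov normality test per group (α = 0.05) into a
  pooled-variance t or a Mann-Whitney U (with normal-approximation z);
  gender by Pearson χ² on the 2×2 counts *without* continuity correction —
  the convention that reproduces the worked example χ² = 0.333, p = 0.564
  for 25/28 vs 29/26.

## Problem sizes used by the test bench

Desk-scale defaults throughout: 12³ grid, 1000 gray-matter voxels, 170
retained volumes, 8 + 8 subjects, 200 Monte-Carlo simulations per
correction (1000 at full scale).  The null study uses 100 cohorts, the
planted-effect study 12, the coupling study 50 cohorts of 50 + 50
subjects.  These sizes were chosen so every study reruns from scratch in
minutes on a single CPU while leaving the statistical questions intact.

## Power margin of the coupling-recovery check

With a realized partial correlation of −0.4 at n = 50 and 3 covariates,
the analytic power of the two-sided α = 0.05 test is
Φ((atanh 0.4 − atanh r_crit)·√43) ≈ 0.80, where r_crit ≈ 0.287 at df = 45.
The acceptance check asks for recovery in ≥ 80% of 50 cohorts — exactly
the expected rate — so individual 50-seed batches fluctuate around the
threshold (observed batches: 0.78, 0.88, 0.80).  This is a property of the
prescribed study conditions, not of the implementation; the generator's
realized coupling is calibrated to the target within 0.01.

## Known limitations

- The phantom's block topology is a stand-in for validating the machinery,
  not a claim about brain network topology.
- Stationary-Gaussian AlphaSim is mildly mis-specified for block-structured
  residuals (see null calibration above); on real data the analogous
  concern is nonstationary smoothness.
- Negative correlations are excluded from FCS by design; no graph metrics
  beyond weighted degree are computed.
- No spatial preprocessing (realignment, slice timing, normalization):
  inputs are assumed already in a common space, as the phantoms are.
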