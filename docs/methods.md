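# Methods

This note documents the models and procedures implemented in `faceatlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic experiments do and do not show.

## Grid model

A `Volume3D` is a 3D scalar array indexed `(i, j, k)` along world `(x, y, z)`
with per-axis millimetre spacing and a world origin; orientation is assumed
identity (volumes are expected to be axis-aligned before export, as is usual
for Cartesian ultrasound exports).  The world coordinate of voxel `(i, j, k)`
is `origin + index * spacing`.  A `SegmentationMask` is a binary grid on the
same convention; its physical volume is `|M| x voxel volume` in mm³.  I/O is
NIfTI-1 and MetaImage via SimpleITK; the proprietary scanner formats are out
of scope.

## Registration

Both stages maximise normalised mutual information,
`NMI = (H(A)+H(B)) / H(A,B)`, from a joint intensity histogram
(64 bins by default, scaled down at coarse pyramid levels).  NMI is bounded
in [1, 2], is 2 for identical (non-constant) images and ≈1 for independent
ones; constant images are degenerate and defined as 2 (both constant) or 1.

Transforms follow the pull-back convention — they map target world
coordinates to moving world coordinates — so resampling is a single pass
over the target grid with no holes.  Out-of-field samples are 0.

**Affine stage.** 12 parameters (3x3 linear block about the volume centre +
translation), optimised by L-BFGS with an analytic gradient of a
Parzen-windowed NMI (hard binning of the fixed image, linear windowing of
the moving image), over an image pyramid built by Gaussian smoothing and
decimation (default factors 4, 2, 1).  The linear block is internally scaled
by the half-extent of the volume so that all 12 parameters move the image by
comparable amounts per unit step.  Everything is deterministic: full-image
histograms, no sampling.

**FFD stage.** Displacement is a cubic B-spline over a control lattice
anchored on the target grid (finest knot spacing 5 voxels, lattice padded by
one control point beyond each face).  The objective is
`NMI − bending_weight × bending energy` with `bending_weight = 1e-3`; the
bending energy is the mean squared second/mixed finite difference of the
lattice coefficients — a discrete thin-plate surrogate that vanishes for any
affine field.  Optimisation is coarse-to-fine over knot spacings (20, 10, 5
voxels by default) with exact cubic-subdivision transfer of coefficients
between levels, L-BFGS with the analytic gradient (the adjoint of the
B-spline expansion "splats" the voxelwise similarity gradient onto the
lattice).  The moving image is pre-resampled through the affine
initialisation once, and the returned transform composes
`T(p) = affine(p + D(p))`.  As a guard, if the optimised field does not
improve the hard-binned NMI over the affine initialisation, the zero field
is returned — the FFD stage can never degrade the similarity.

Convergence: relative objective change below `1e-5` or 300 L-BFGS iterations
per level.  The experiment harnesses use a faster affine-only setting
(pyramid factors 4 and 2, 40 iterations, 32 bins) where hundreds of
registrations are needed; see "Problem sizes" below.

## Label fusion

Propagated masks are linearly resampled, giving probabilistic votes in
[0, 1].  Per voxel, atlases are ranked by LNCC — Pearson correlation of
target and warped atlas image under a Gaussian window (σ = 2 mm default;
zero-variance windows are defined as 0) — and the `top_k = 8` best are kept,
ties broken toward the lower atlas index.  The selected votes are combined
by a STAPLE-style EM: the truth posterior is computed from current
sensitivities/specificities with a global prior fixed at the mean vote rate,
and per-atlas (p, q) are re-estimated over the voxels where that atlas is
selected.  Probabilistic votes enter the likelihood geometrically
(`p^d (1−p)^(1−d)`), reducing to classical STAPLE for binary votes.  The EM
initialises the posterior at the mean of the selected votes and runs the
M-step first (the classical ordering); it stops when the mean posterior
changes by less than `1e-4` (relative) or after 30 iterations.  The
posterior is thresholded at exactly 0.5, ties to foreground.

Spatial regularisation (the MRF of full STEPS implementations) is replaced
by an optional Gaussian smoothing of the posterior before thresholding.  It
is **off by default**: smoothing shifts boundaries by curvature, which would
break the fuser's exact degenerate-case behaviour (single atlas in = that
vote out; unanimous perfect atlases = truth exactly; uniform similarity with
EM off = per-voxel majority vote).  Set
`FusionParams(posterior_smoothing_sigma_vox=1.0)` to enable it.

## Agreement metrics

Surfaces are the foreground voxels with at least one background 6-neighbour;
the grid border counts as background.  Distances are Euclidean between voxel
centres in world mm, computed with an exact distance transform honouring
anisotropic spacing (the brute-force full pairwise scan is reserved for test
oracles).  Conventions for degenerate inputs: Dice(∅, ∅) := 1 (with a
warning), ASSD is an error for empty masks, diffVol is an error for two
empty masks and 200% when exactly one is empty.  An optional
region-of-interest restriction of the surfaces is not implemented; the full
boundary is always used.

## Statistics

- **Friedman** across repeated conditions: tie-corrected statistic
  `(k−1) Σ_j (R_j − n(k+1)/2)² / Σ_ij (r_ij − (k+1)/2)²`.  For small tables
  (≤ ~20 000 within-case permutations) the p-value is the exact permutation
  tail — the χ² approximation misstates small-sample p-values by up to ~0.2
  — otherwise the χ²(k−1) tail.
- **Kruskal–Wallis** with tie correction; exact permutation p for designs
  with ≤ ~50 000 assignments, χ²(g−1) otherwise.
- **Post hoc**: Wilcoxon signed-rank for paired condition comparisons (rater
  pairings share cases), Mann–Whitney U for independent groups, flagged at
  the Bonferroni-adjusted level α/m (0.05/3 ≈ 0.017 for three comparisons,
  0.05/6 ≈ 0.0083 for six).
- **ICC**: two-way, absolute agreement, single measure — ICC(A,1) =
  `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` from repeated-measures
  ANOVA mean squares; the consistency form ICC(C,1) is available via
  `form="C-1"`.  Zero between-case variance is an error.  Cross-checked
  against pingouin in the test suite.
- **Volume trend**: two-sided t-test on the OLS slope of a per-case mean
  metric against the cube root of segmentation volume, n−2 df; an exact fit
  reports p = 0.
- **Effect size**: (mean inter − mean intra) / pooled SD, reported but not
  tested.

## Synthetic phantoms

The generator emulates an axis-aligned Cartesian export of a fetal-face
sweep on a 64³ grid at 1 mm isotropic by default (48³ for the heavier
experiments, 96³ for demo runs; the voxel spacing of real exports is
scanner-dependent, so 1 mm is a neutral default).  The template is a
half-ellipsoid "head" facing +y with a nasal protrusion and two orbital
indentations; per-subject anatomy applies a smooth random warp (Gaussian
field, σ = 8 voxels) scaled to a given RMS magnitude — 3 mm in the cohort
experiments.  The image is piecewise tissue intensity (face 0.75 ± slow
variation, maternal tissue 0.45, anechoic amniotic fluid 0.10 in front of
the face), optional limb/cord-like clutter touching the face
(probability 0.3), and multiplicative speckle: a Gaussian-smoothed
(σ = 1 voxel) noise field at 35 % contrast.  This stresses intensity-based
registration and fusion but is not a physical scatterer simulation: no probe
geometry, beamforming, shadowing, depth-dependent resolution or fetal-pose
variation beyond the smooth warp.  Passing tests therefore demonstrate the
pipeline's correctness and its qualitative behaviour (atlas-size effect,
rater-variability direction), not clinical-grade accuracy on real
ultrasound.

Simulated raters perturb a truth mask with a volume bias (a level-set shift
of the boundary hitting exactly the target voxel count; ties at the cut are
broken deterministically) followed by a smooth boundary jitter of given RMS
amplitude (σ = 3 voxels field).  Zero noise reproduces the truth bit for
bit.  In the four-rater design (three operators, one repeated), the repeat
re-perturbs the first operator's mask with the intra-session jitter;
setting the intra jitter to None makes the repeat an independent rater — the
exchangeable null under which the Friedman test should not reject.

## Problem sizes used in the shipped experiments

- Known-warp recovery: one 64³ subject, 3 mm B-spline warp, full-quality
  affine+FFD registration (~20 s).
- Growing-atlas effect: 5 replicate cohorts of 40 subjects at 48³ (3 mm
  deformation); 10 held-out cases compared at 10 vs 30 references with the
  fast affine-only registration setting, registrations cached across atlas
  sizes (~75 s per replicate).
- STAPLE recovery: 6 raters at (p, q) = (0.90, 0.95) on a 30³ ellipsoid
  truth occupying ~27 % of the grid — large enough that each rater's
  empirical flip rate concentrates within ~0.01 of nominal, so estimator
  error is measured rather than generative sampling noise.
- Rater study: 15 subjects at 48³, inter jitter 1 mm, intra jitter 0.5 mm,
  10 seeded runs.

## Known limitations

- Registration assumes identity orientation and roughly overlapping fields
  of view; there is no initial center-of-mass alignment step.
- The FFD is not guaranteed diffeomorphic; large warps can fold.
- Fusion is binary (two classes) only.
- The exact permutation p-values switch to the χ² approximation above the
  enumeration ceilings; in the transition region the approximation error is
  not controlled.
- The rater simulator models boundary uncertainty and volume bias, not
  structured disagreement (e.g. systematically different anatomical
  interpretations).
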