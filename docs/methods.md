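# Methods

This note records the models, conventions, numerical choices, and known
limitations behind `enterometry`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Spatial conventions

All modules share one physical frame: axis-aligned millimetre coordinates
with the origin at the grid corner and the centre of voxel `(i, j, k)` at
`origin + ((i, j, k) + 0.5) · spacing`. Axes 0–1 are the in-plane
(coronal) axes, axis 2 the through-plane slice axis. The default spacing,
1.3 × 1.3 × 5.0 mm, mimics a coronal T2-weighted single-shot fast-spin-echo
(SSFSE) enterography acquisition (≈1.3 mm in-plane from a 280 mm FOV at a
~216 matrix; 5 mm sections). NIfTI-1 is the sole volume/mask format;
because its header stores zooms in float32, spacing is rounded to 1e-6 mm
on read so mm-scale spacings round-trip exactly.

## Phantom generator

A phantom is a tube following a smooth 3D curve: a natural cubic spline
through control points, densely resampled at ≤ min(spacing)/4. Voxel
centres within `lumen_radius` of the curve become lumen, within
`lumen_radius + wall_thickness` wall, otherwise background; voxels whose
nearest curve sample is an endpoint are background, giving flat end caps
so the noise-free wall volume equals the analytic annulus integral
∫ π((r+t(s))² − r²) ds (trapezoid over the dense curve). Wall thickness
may be a scalar or a function of normalized arc length; the built-in
cosine ramp `t(u) = t0 + (t1−t0)(1−cos πu)/2` has arc-mean exactly
`(t0+t1)/2`, which exercises the mean-vs-max thickness distinction.

Intensities default to background/wall/lumen = 40/110/200 with additive
Gaussian noise (σ = 10); a Rician option (magnitude of a complex signal
with iid Gaussian parts) is available but Gaussian is the default so the
acceptance arithmetic stays closed-form. No published intensity statistics
exist for inflamed wall vs lumen on SSFSE, so the triplet is an explicit
config parameter, and no test depends on its specific values.

The generator does *not* simulate peristalsis, fat stranding, strictures
with upstream dilation, skip lesions, partial-volume blur, or bias fields.
Passing phantom tests therefore demonstrates correctness of the geometry
and measurement operators, not clinical performance on patient MRI.

### Voxelization error and phantom geometry in tests

Two discretization effects shaped the validation fixtures:

- A 3 mm wall shell is only ~2.3 px thick at 1.3 mm in-plane sampling, and
  annulus voxel counts can deviate up to ~6% depending on how the tube axis
  aligns with the pixel grid. The analytic-volume checks therefore sample
  at 0.8 mm in-plane, where the error stays ≤ 3% across alignments; the
  default clinical spacing is unchanged elsewhere.
- With 5 mm slices, a tube whose axis lies *in* the coronal plane presents
  near-tangent cross-sections in the outermost slices, which 2D slice-wise
  thickness systematically overestimates (a property of slice-wise
  thickness, not a bug). Constant-thickness recovery fixtures therefore run
  the tube along the slice normal, so every slice cuts the annulus
  transversely. The tangent-slice bias for strongly in-plane segments is a
  documented limitation of the 2D thickness definition.

## Centerline and length of disease

The centerline interpolates (not approximates) the ordered seeds with a
natural cubic spline on chord-length parameterization, then resamples at
an approximately uniform arc step (default 0.5 mm, well under the in-plane
spacing; halving the step changes length by < 0.1%). The seed parameter
values are always included in the sample set, so the polyline passes
through every seed exactly. Exact consecutive duplicate seeds are
collapsed (first occurrence kept) with a warning; an all-identical seed
set is rejected. Length of disease is the final cumulative arc length,
reported in cm. The analytic checks (quarter arc r = 50 mm, two-turn
helix) recover closed-form lengths to ≪ 1%. The vendor tools used in
clinical studies do not document their interpolation family, so only
internal-consistency properties (rigid invariance, chord bound,
refinement, seed-density convergence) are asserted — no equivalence with
any specific product.

## Semi-automated segmentation

The operator contributes only the centerline. Within a region of interest
(all voxels within `roi_radius_mm = 20` of the centerline), k-means
(k = 40, `n_init = 3`, fixed seed) clusters voxels in a feature space of
standardized intensity plus spatially weighted coordinates; the spatial
weight (default 0.5) divides mm coordinates by the equal-share partition
pitch `(ROI volume / k)^{1/3}`, an SLIC-like compactness trade-off. Each
cluster is split into face-connected (6-connectivity) components, so every
partition is contiguous by construction — asserted on every run in tests.

Each partition is summarized by nine features: mean and SD intensity,
voxel count, physical volume, min and mean distance to the centerline,
elongation (ratio of extreme principal-axis lengths of the mm coordinate
covariance, floored at half the smallest spacing; 1 for a single voxel),
mean gradient magnitude on the partition boundary, and the fraction of
voxels inside the wall-band annulus `[r_lumen, r_lumen + 6 mm]`. The set
covers the three signals a centerline-guided segmenter can use — intensity,
shape, and centerline-relative position — and is config-extensible; the
schema is hashed into the trained model, which refuses mismatched tables.

A random-forest regressor (200 trees, fixed seed) is trained on phantom
partitions against *soft* targets — the fraction of each partition inside
the true wall — matching the "probability of forming part of the final
segmentation" framing rather than a hard classifier. Assembly takes the
union of partitions with predicted probability ≥ threshold (default 0.5,
ties include), removes all voxels inside the geometric lumen band
(enforcing lumen exclusion even when the model errs), and keeps only
face-connected components touching the wall-band annulus. An empty result
is a valid output (warning, not error). All pipeline stages are
deterministic given seeds.

Manual masks are validated rather than produced: voxels inside the lumen
band or beyond a distance band from the centerline are stripped if they are
a small fraction (≤ 1% lumen, ≤ 5% out-of-band) and raise otherwise.

The pipeline runs in 3D with anisotropic spacing. It is this package's own
design throughout — cluster count, features, threshold, and post-processing
are not published for any commercial tool and no equivalence is claimed.

## Morphometry

Volume is `voxel count × voxel volume / 1000` (mL), exact and additive;
rounding to the reporting precision (0.1 mL, 0.1 cm, 0.1 mm) happens only
at the reporting/CLI layer. Wall thickness is deliberately 2D slice-wise:
the source images have 5 mm slices, and a 3D distance transform would be
dominated by the slice direction. Per coronal slice, the Euclidean
distance transform (physical in-plane sampling) is evaluated at medial
pixels — the 2D morphological skeleton — and local thickness is
`2·EDT − s/2` with `s` the in-plane pitch: the EDT measures to background
pixel *centres*, which lie between 0 (curved interfaces) and s/2
(axis-aligned flat interfaces) beyond the true interface, so a quarter
pixel per side is subtracted as the midpoint correction. Slices nowhere
thicker than one pixel carry no sub-pixel information: their thickness
saturates at the pixel pitch and an all-thin mask is flagged
low-confidence. The profile's mean is the mean-wall-thickness biomarker;
its maximum is an automated *analogue* of the radiologist's single manual
caliper, kept as a separate column and never conflated with it.

## Cohort simulation

Two simulators feed the statistics layer:

- `make_longitudinal_cohort` draws measurement tables directly: value =
  baseline mean × per-timepoint shrink factor × exp(bᵢ + e), with a
  subject severity intercept bᵢ ~ N(0, 0.6²) shared across measurements
  (log-scale SD 0.6 matches the ≈0.65 coefficient of variation of baseline
  manual volume in the reference cohort) and cell noise e ~ N(0, 0.2²).
  Defaults are the reference study conditions: n = 20 subjects, visits at
  diagnosis / 6 weeks / 6 months, baseline means (7.6 mm max thickness,
  3.6 mm mean thickness, 19.2 cm length, 19.8 mL manual volume, 24.0 mL
  semi-automated volume) and the shrink factors implied by the reported
  follow-up means; optional missingness flags reproduce the study's three
  incomplete subjects (one baseline-only, two missing month 6).
- `simulate_imaging_study` builds an actual phantom per subject-visit
  (baseline wall thickness ~6 mm × lognormal(0.15) clipped to [4.5, 8.5],
  length ~140 mm × lognormal(0.25) clipped to [80, 200] so grids stay
  tractable, lumen radius U(4, 6)), shrinks thickness and length
  multiplicatively over visits, and measures every visit as a reader
  would: "manual" masks are operator-perturbed truth (random add/remove of
  boundary shells, ~few % volume jitter), lengths come from jittered-seed
  centerlines, semi-automated volumes from the full pipeline.

## Statistics

- **Change over time**: linear mixed model `y ~ timepoint` with a random
  subject intercept, REML. Random intercept only — the smallest structure
  consistent with repeated measures at n = 20 × 3; no random slope. The
  p-value is the joint Wald χ² test of the two timepoint fixed effects;
  Monte-Carlo calibration over 500 null cohorts (recomputed in the
  acceptance suite) keeps the type-I error within [0.03, 0.08] at
  α = 0.05. Missing visits are handled by likelihood on available data; no
  imputation. No multiplicity correction is applied anywhere (single
  pre-specified α = 0.05).
- **Percent change** is computed from *group means*,
  `100·(x̄_base − x̄_follow)/x̄_base`, rounded to integer percent
  (half away from zero; positive = decrease). The change-of-means
  definition is the one consistent with reporting percent declines next to
  group means; a per-subject-change variant is available via
  `rounded=False` composition but is not the default.
- **Agreement**: ICC(2,1) — two-way random effects, absolute agreement,
  single measures — computed directly from the two-way ANOVA mean squares,
  with the standard F-distribution confidence interval. Absolute agreement
  is chosen because the question is interchangeability of manual and
  semi-automated volumes, not mere consistency. Bands: < 0.50 poor,
  0.50–0.75 moderate, 0.75–0.90 good, > 0.90 excellent. Zero variance in
  both raters raises (ICC undefined). The implementation is cross-checked
  in tests against an independent OLS/ANOVA decomposition (1e-9) and
  against `pingouin`.
- **Correlation**: Pearson r via `scipy.stats.pearsonr` with Fisher-z 95%
  CI and two-sided p; pairwise deletion of missing values; ≥ 4 complete
  pairs; zero variance raises. The study-level bundle pools all visits, as
  agreement/correlation analyses of such cohorts conventionally do.

## Problem sizes

Validation runs use deliberately compact problems chosen to make the
checks sharp rather than large: ~50–100k-voxel phantom grids, 30 training
phantoms and 5 held-out phantoms for segmentation accuracy, a 20 × 3
simulated imaging cohort, 500 Monte-Carlo null cohorts for test
calibration, and 300-case fuzzing for the ICC/Pearson oracles.

## Known limitations

- Slice-wise thickness overestimates on segments running tangent to the
  slice plane (above); mean thickness on strongly in-plane anatomy
  inherits that bias.
- The max-thickness column is an automated profile maximum, not a human
  caliper; the two can differ systematically on real images.
- The phantom world contains a single contiguous segment with a circular
  cross-section; partial-volume effects, luminal debris, and neighbouring
  bowel loops — the main failure modes of real semi-automated segmentation
  — are absent, so held-out Dice here is an upper bound on realism.
- ICC/correlation results on simulated cohorts characterize the
  implementation, not any clinical population; agreement between
  perturbed-truth "manual" masks and the pipeline is naturally higher than
  between two independent human processes.
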