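# enterometry

Linear and volumetric measurement of ileal bowel-wall inflammation on MR
enterography-like image volumes, with a synthetic-phantom validation layer
and the longitudinal statistics used in treatment-response imaging studies.

## Who this is for

Quantitative-imaging researchers who need the full measurement chain of a
Crohn-disease enterography study as reproducible, testable code:

- **Length of disease** — a smooth centerline interpolated through operator
  seed points placed along the bowel lumen; the biomarker is its arc length
  (cm). The interpolant is a natural cubic spline on a chord-length
  parameterization, so the curve passes exactly through every seed.
- **Bowel-wall segmentation** — two routes to a wall-only mask (outer
  serosa to inner mucosa, lumen excluded): validation/cleaning of a manual
  mask, and a semi-automated centerline-guided pipeline: contiguous k-means
  partitions of the centerline neighbourhood → per-partition feature
  vectors → a random-forest regressor scoring each partition's probability
  of being wall → assembly of high-probability partitions with a hard
  geometric lumen exclusion.
- **Morphometry** — disease volume (mL) by voxel counting, and mean/max
  wall thickness (mm) by the distance-transform construction: per coronal
  slice, thickness at each medial (skeleton) pixel is twice the Euclidean
  distance transform there, averaged over all medial pixels.
- **Longitudinal statistics** — change over time by a linear mixed-effects
  model (fixed categorical timepoint, random subject intercept, REML, joint
  Wald test), group-mean percent change
  `100·(baseline − followup)/baseline`, agreement between manual and
  semi-automated volumes by ICC(2,1) (two-way random effects, absolute
  agreement, single measures, F-based CI), and Pearson correlations with
  Fisher-z intervals.

Because no patient images ship with a study like this, the package includes
a first-class phantom generator: bright-lumen tubes following smooth 3D
curves with an intermediate-intensity wall shell at SSFSE-like anisotropic
spacing (1.3 × 1.3 × 5 mm), with exact analytic ground truth (wall mask,
centerline, length, annulus volume, thickness profile) so every operator in
the chain is checked against closed-form values.

## Worked example

```python
import numpy as np
import enterometry as em
from enterometry.morphometry import mask_volume_mL

# a straight inflamed segment: lumen r=5 mm, wall 3 mm, length 100 mm
n, s = 60, 0.8
c = n * s / 2
spec = em.PhantomSpec(
    grid_shape=(n, n, 27), spacing=(s, s, 5.0),
    curve_control_points=np.array([[c, c, 15.0], [c, c, 65.0], [c, c, 115.0]]),
    lumen_radius_mm=5.0, wall_thickness_mm=3.0, noise_sigma=0.0)
volume, truth = em.make_phantom(spec)
print(round(truth.true_volume_mL, 2), round(mask_volume_mL(truth.wall_mask), 2))
```

prints `12.25 12.54`: the analytic annular-cylinder volume
π·(8² − 5²)·100/1000 = 12.25 mL, and the voxel-counted truth-mask volume
(+2.4% voxelization error). The `examples/` directory has one short script
per capability (phantoms, disease length, semi-automated segmentation,
wall thickness, longitudinal statistics); each prints the numbers it
computes and what they mean. Running `examples/05_longitudinal_statistics.py`
on a simulated 20-subject cohort prints, e.g., mixed-effects p-values
< 0.001 for all five measurements, manual-volume percent declines of
39%/71% at the two follow-ups, and
`ICC(2,1) manual vs semi-automated volume: 0.84 [0.27-0.94] (good)`.

A thin CLI wraps the same functions:

```bash
enterometry simulate --spec spec.json --seed 3 --out phantom/
enterometry length   --seeds phantom/seeds.json
enterometry segment  --mode semiauto --volume v.nii.gz --seeds s.json --model m.bin --out mask.nii.gz
enterometry measure  --mask mask.nii.gz --seeds s.json
enterometry stats    --table cohort.csv --out results/
```

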