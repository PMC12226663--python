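"""Synthetic enterography phantoms with exact ground truth.

The phantom emulates the appearance of an inflamed ileal segment on a
coronal T2-weighted single-shot fast-spin-echo (SSFSE) acquisition: a
bright fluid-filled lumen following a smooth 3D curve, an
intermediate-intensity thickened wall shell around it, a darker
background, and additive noise.  Voxel spacing defaults to
1.3 x 1.3 x 5.0 mm (in-plane x slice thickness), the geometry typical of
paediatric small-bowel SSFSE enterography.

Ground truth (wall mask, centerline, analytic length / annulus volume /
mean wall thickness) is computed from the generating curve, so every
downstream measurement can be validated against closed-form values.

A companion generator produces longitudinal measurement cohorts (subject
x timepoint tables) with multiplicative treatment effects on a log-normal
subject baseline, mimicking a three-visit anti-TNF treatment-response
study design (diagnosis, 6 weeks, 6 months).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .centerline import Centerline, interpolate_centerline, _cumulative_arc
from .image import ImageVolume, SegmentationMask, SeedPointSet

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_phantom",
    "cosine_ramp_thickness",
    "make_longitudinal_cohort",
    "MEASUREMENTS",
    "REFERENCE_BASELINE_MEANS",
    "REFERENCE_SHRINK_FACTORS",
    "TIMEPOINTS",
]

TIMEPOINTS = ("baseline", "week6", "month6")

MEASUREMENTS = (
    "max_thickness_mm",
    "mean_thickness_mm",
    "length_cm",
    "manual_volume_mL",
    "semiauto_volume_mL",
)

#: Group means typical of newly diagnosed paediatric ileal Crohn disease at
#: diagnosis, used as cohort-generator defaults (units per MEASUREMENTS).
REFERENCE_BASELINE_MEANS: Mapping[str, float] = {
    "max_thickness_mm": 7.6,
    "mean_thickness_mm": 3.6,
    "length_cm": 19.2,
    "manual_volume_mL": 19.8,
    "semiauto_volume_mL": 24.0,
}

#: Multiplicative per-timepoint treatment effects (baseline, 6 weeks,
#: 6 months) matching the reference group means under anti-TNF therapy.
REFERENCE_SHRINK_FACTORS: Mapping[str, tuple[float, float, float]] = {
    "max_thickness_mm": (1.0, 5.8 / 7.6, 4.5 / 7.6),
    "mean_thickness_mm": (1.0, 3.3 / 3.6, 2.6 / 3.6),
    "length_cm": (1.0, 12.2 / 19.2, 8.0 / 19.2),
    "manual_volume_mL": (1.0, 11.6 / 19.8, 5.1 / 19.8),
    "semiauto_volume_mL": (1.0, 15.1 / 24.0, 9.1 / 24.0),
}


def cosine_ramp_thickness(start_mm: float, end_mm: float) -> Callable[[np.ndarray], np.ndarray]:
    """Smooth wall-thickness profile along normalized arc length u in [0, 1].

    t(u) = start + (end - start) * (1 - cos(pi u)) / 2; arc-averaged mean is
    exactly (start + end) / 2 and the maximum is max(start, end).
    """
    def profile(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        return start_mm + (end_mm - start_mm) * (1.0 - np.cos(np.pi * u)) / 2.0
    return profile


@dataclass
class PhantomSpec:
    """Geometry, intensity, and noise parameters of a bowel phantom.

    ``wall_thickness_mm`` may be a scalar or a callable of normalized arc
    length u in [0, 1] (variable-thickness phantoms).
    """

    grid_shape: tuple[int, int, int] = (96, 96, 32)
    spacing: tuple[float, float, float] = (1.3, 1.3, 5.0)
    curve_control_points: np.ndarray = field(
        default_factory=lambda: np.array([[20.0, 62.4, 80.0], [62.4, 62.4, 80.0], [104.8, 62.4, 80.0]])
    )
    lumen_radius_mm: float = 5.0
    wall_thickness_mm: float | Callable[[np.ndarray], np.ndarray] = 3.0
    intensity_background: float = 40.0
    intensity_wall: float = 110.0
    intensity_lumen: float = 200.0
    noise_sigma: float = 10.0
    noise_model: str = "gaussian"  # or "rician"
    rng_seed: int = 0

    def thickness_at(self, u: np.ndarray) -> np.ndarray:
        if callable(self.wall_thickness_mm):
            return np.asarray(self.wall_thickness_mm(u), dtype=float)
        return np.full(np.shape(u), float(self.wall_thickness_mm))

    def validate(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen_radius_mm must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        t = self.thickness_at(np.linspace(0, 1, 64))
        if np.any(t <= 0):
            raise ValueError("wall_thickness_mm must be positive along the whole segment")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        pts = np.asarray(self.curve_control_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("curve_control_points must be an (n>=2, 3) array of mm coordinates")


@dataclass
class PhantomTruth:
    """Exact ground truth accompanying a generated phantom volume."""

    wall_mask: SegmentationMask
    lumen_mask: SegmentationMask
    centerline: Centerline
    true_length_cm: float
    true_volume_mL: float
    true_mean_thickness_mm: float
    true_max_thickness_mm: float
    spec: PhantomSpec


def _dense_curve(spec: PhantomSpec) -> Centerline:
    step = min(spec.spacing) / 4.0
    seeds = SeedPointSet(points=np.asarray(spec.curve_control_points, dtype=float))
    return interpolate_centerline(seeds, step_mm=step)


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, PhantomTruth]:
    """Rasterize a tube phantom and return the image plus its ground truth.

    Classification happens at voxel centres against the densely resampled
    generating curve: centres within ``lumen_radius`` of the curve are
    lumen, within ``lumen_radius + wall_thickness`` are wall, otherwise
    background.  Voxels whose nearest curve sample is an endpoint are
    treated as beyond the segment (flat end caps), so the noise-free wall
    volume matches the analytic annulus integral.
    """
    spec.validate()
    cl = _dense_curve(spec)
    curve = cl.points
    s = cl.cumulative_length_mm
    length_mm = cl.length_mm
    u = s / length_mm if length_mm > 0 else s
    t_profile = spec.thickness_at(u)

    # The curve must stay inside the grid with a margin >= lumen + wall.
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    margin_needed = spec.lumen_radius_mm + t_profile
    low = curve - margin_needed[:, None]
    high = curve + margin_needed[:, None]
    if np.any(low < 0) or np.any(high > extent[None, :]):
        raise ValueError(
            "curve exits the grid: the tube (lumen + wall) must fit inside "
            f"the {extent} mm extent with its full radius as margin"
        )

    centers = np.stack(np.meshgrid(
        *[(np.arange(n) + 0.5) * sp for n, sp in zip(spec.grid_shape, spec.spacing)],
        indexing="ij",
    ), axis=-1).reshape(-1, 3)
    tree = cKDTree(curve)
    max_reach = spec.lumen_radius_mm + float(np.max(t_profile)) + 2.0 * max(spec.spacing)
    dist, idx = tree.query(centers, distance_upper_bound=max_reach)
    interior = np.isfinite(dist) & (idx > 0) & (idx < len(curve) - 1)
    t_here = np.zeros(len(centers))
    t_here[interior] = t_profile[idx[interior]]

    lumen = interior & (dist <= spec.lumen_radius_mm)
    wall = interior & (dist > spec.lumen_radius_mm) & (dist <= spec.lumen_radius_mm + t_here)

    img = np.full(len(centers), spec.intensity_background, dtype=float)
    img[wall] = spec.intensity_wall
    img[lumen] = spec.intensity_lumen
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.rng_seed)
        if spec.noise_model == "gaussian":
            img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
        else:  # rician: magnitude of complex signal with iid gaussian parts
            n1 = rng.normal(0.0, spec.noise_sigma, size=img.shape)
            n2 = rng.normal(0.0, spec.noise_sigma, size=img.shape)
            img = np.sqrt((img + n1) ** 2 + n2 ** 2)

    shape = tuple(spec.grid_shape)
    volume = ImageVolume(voxels=img.reshape(shape), spacing=spec.spacing)
    wall_mask = SegmentationMask(voxels=wall.reshape(shape), spacing=spec.spacing)
    lumen_mask = SegmentationMask(voxels=lumen.reshape(shape), spacing=spec.spacing)

    r = spec.lumen_radius_mm
    annulus_area = np.pi * ((r + t_profile) ** 2 - r ** 2)  # mm^2 along arc
    true_volume_mL = float(np.trapezoid(annulus_area, s) / 1000.0)
    true_mean_thickness = float(np.trapezoid(t_profile, s) / length_mm)
    truth = PhantomTruth(
        wall_mask=wall_mask,
        lumen_mask=lumen_mask,
        centerline=cl,
        true_length_cm=length_mm / 10.0,
        true_volume_mL=true_volume_mL,
        true_mean_thickness_mm=true_mean_thickness,
        true_max_thickness_mm=float(np.max(t_profile)),
        spec=spec,
    )
    return volume, truth


def make_longitudinal_cohort(
    n_subjects: int = 20,
    timepoint_effects: Mapping[str, Sequence[float]] | Sequence[float] | None = None,
    between_subject_sd: float = 0.6,
    within_subject_sd: float = 0.2,
    baseline_means: Mapping[str, float] | None = None,
    n_missing_month6: int = 0,
    n_missing_all_followup: int = 0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Simulate a subject x timepoint measurement table.

    Each measurement is ``baseline_mean * shrink[timepoint] * exp(b_i + e)``
    with a subject-level severity intercept ``b_i ~ N(0, between_sd^2)``
    shared across measurements (so manual and semi-automated volumes of the
    same subject co-vary) and independent log-scale noise
    ``e ~ N(0, within_sd^2)`` per cell.  Multiplicative shrink factors model
    the treatment effect; missing-at-followup flags remove rows to mimic
    subjects lost to follow-up or resected before the final visit.

    Returns a long-format table: one row per (subject, timepoint), columns
    per MEASUREMENTS; missing visits are absent rows.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2 for a longitudinal design")
    if between_subject_sd < 0 or within_subject_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    if n_missing_month6 + n_missing_all_followup > n_subjects:
        raise ValueError("more missing subjects than subjects")

    if baseline_means is None:
        baseline_means = REFERENCE_BASELINE_MEANS
    if timepoint_effects is None:
        effects = {m: REFERENCE_SHRINK_FACTORS[m] for m in MEASUREMENTS}
    elif isinstance(timepoint_effects, Mapping):
        effects = {m: tuple(timepoint_effects[m]) for m in MEASUREMENTS}
    else:
        effects = {m: tuple(timepoint_effects) for m in MEASUREMENTS}
    for m, f in effects.items():
        if len(f) != len(TIMEPOINTS):
            raise ValueError(f"{m}: need one shrink factor per timepoint")
        if any(not (0 < x <= 1) for x in f):
            raise ValueError(f"{m}: shrink factors must lie in (0, 1]")

    rng = np.random.default_rng(rng_seed)
    intercepts = rng.normal(0.0, between_subject_sd, size=n_subjects)
    # Mirror a real cohort's attrition: the first `n_missing_all_followup`
    # subjects have baseline only; the next `n_missing_month6` miss month 6.
    rows = []
    for i in range(n_subjects):
        subject = f"S{i + 1:03d}"
        for ti, tp in enumerate(TIMEPOINTS):
            if i < n_missing_all_followup and tp != "baseline":
                continue
            if n_missing_all_followup <= i < n_missing_all_followup + n_missing_month6 \
                    and tp == "month6":
                continue
            row = {"subject_id": subject, "timepoint": tp}
            for m in MEASUREMENTS:
                noise = rng.normal(0.0, within_subject_sd)
                row[m] = baseline_means[m] * effects[m][ti] * np.exp(intercepts[i] + noise)
            rows.append(row)
    return pd.DataFrame(rows)
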