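"""Centerline construction and disease-length measurement.

The inflamed segment's length is measured by interpolating a smooth curve
("centerline") through operator seed points placed along the bowel lumen
and integrating its arc length.  The interpolant is a natural cubic spline
on a chord-length parameterization, so the curve passes exactly through
every seed; it is then resampled at a fine, approximately uniform arc-length
step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy.interpolate import CubicSpline

from .image import SeedPointSet

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import PhantomTruth

__all__ = [
    "Centerline",
    "interpolate_centerline",
    "centerline_length",
    "centerline_from_truth",
]

#: Default resampling step.  Well below the ~1.3 mm in-plane spacing of the
#: target images, so length error is dominated by seed placement, not by
#: polyline discretization.
DEFAULT_STEP_MM = 0.5


@dataclass
class Centerline:
    """Densely sampled ordered curve in physical space with arc length."""

    points: np.ndarray                 # (m, 3) mm
    cumulative_length_mm: np.ndarray   # (m,) nondecreasing, starts at 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.cumulative_length_mm = np.asarray(self.cumulative_length_mm, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline points must be an (m, 3) array")
        if self.cumulative_length_mm.shape != (self.points.shape[0],):
            raise ValueError("cumulative length must have one entry per point")
        if self.cumulative_length_mm[0] != 0.0:
            raise ValueError("cumulative length must start at 0")
        if np.any(np.diff(self.cumulative_length_mm) < 0):
            raise ValueError("cumulative length must be nondecreasing")

    @property
    def length_mm(self) -> float:
        return float(self.cumulative_length_mm[-1])

    @property
    def length_cm(self) -> float:
        return self.length_mm / 10.0


def _cumulative_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _collapse_duplicate_seeds(pts: np.ndarray) -> np.ndarray:
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0.0, axis=1)
    if not keep.all():
        warnings.warn(
            f"collapsed {int((~keep).sum())} duplicate consecutive seed point(s), "
            "keeping first occurrence",
            stacklevel=3,
        )
    return pts[keep]


def interpolate_centerline(seeds: SeedPointSet, step_mm: float = DEFAULT_STEP_MM) -> Centerline:
    """Interpolate a smooth curve through ordered seed points.

    Parameters
    ----------
    seeds
        Ordered seed points along the lumen, physical mm.
    step_mm
        Target arc-length resampling step; the output is sampled at most
        this far apart and always includes the seed locations themselves.

    Returns
    -------
    Centerline
        Curve through every seed (natural cubic spline, chord-length
        parameterized), endpoints equal to the first and last seeds.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    pts = _collapse_duplicate_seeds(np.asarray(seeds.points, dtype=float))
    if len(pts) < 2:
        raise ValueError("all seed points are identical; cannot build a centerline")

    t = _cumulative_arc(pts)  # chord-length parameter
    if len(pts) == 2:
        def curve(u):  # straight segment
            u = np.atleast_1d(u)
            w = (u / t[-1])[:, None]
            return (1 - w) * pts[0] + w * pts[1]
    else:
        spline = CubicSpline(t, pts, axis=0, bc_type="natural")
        curve = spline

    # Oversample to estimate arc length, then invert s(t) for uniform steps.
    fine_t = np.unique(np.concatenate(
        [np.linspace(t[i], t[i + 1], 64, endpoint=False) for i in range(len(t) - 1)]
        + [t[-1:]]
    ))
    fine_pts = np.asarray(curve(fine_t))
    fine_s = _cumulative_arc(fine_pts)
    total = fine_s[-1]

    n_out = max(int(np.ceil(total / step_mm)) + 1, 2)
    target_s = np.linspace(0.0, total, n_out)
    # strictly increasing s is required for interpolation; dedupe
    keep = np.concatenate([[True], np.diff(fine_s) > 0])
    out_t = np.interp(target_s, fine_s[keep], fine_t[keep])
    out_t = np.unique(np.concatenate([out_t, t]))  # guarantee exact seed passage
    out_pts = np.asarray(curve(out_t))
    return Centerline(points=out_pts, cumulative_length_mm=_cumulative_arc(out_pts))


def centerline_length(cl: Centerline) -> float:
    """Total arc length of the centerline in cm (the length of disease)."""
    return cl.length_cm


def centerline_from_truth(
    truth: "PhantomTruth",
    n_seeds: int,
    jitter_mm: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SeedPointSet:
    """Emulate an operator placing seeds along a phantom's true lumen curve.

    Seeds are sampled at equal arc-length spacing from the ground-truth
    centerline; optional isotropic jitter (uniform in a ball of radius
    ``jitter_mm``) mimics imprecise clicking.  Jitter larger than the lumen
    radius would place seeds outside the lumen and is rejected.
    """
    if n_seeds < 2:
        raise ValueError("n_seeds must be >= 2")
    if jitter_mm < 0:
        raise ValueError("jitter_mm must be nonnegative")
    if jitter_mm > truth.spec.lumen_radius_mm:
        raise ValueError(
            f"jitter_mm={jitter_mm} exceeds the lumen radius "
            f"{truth.spec.lumen_radius_mm} mm; seeds must stay inside the lumen"
        )
    cl = truth.centerline
    target_s = np.linspace(0.0, cl.length_mm, n_seeds)
    seeds = np.stack([
        np.interp(target_s, cl.cumulative_length_mm, cl.points[:, ax])
        for ax in range(3)
    ], axis=1)
    if jitter_mm > 0:
        rng = np.random.default_rng(rng)
        # uniform in a ball: direction * radius with r ~ U^(1/3)
        direction = rng.normal(size=seeds.shape)
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = jitter_mm * rng.random(len(seeds)) ** (1 / 3)
        seeds = seeds + direction * radius[:, None]
    return SeedPointSet(points=seeds)
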