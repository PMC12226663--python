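"""Shared spatial containers for enterography-style volumes.

All physical coordinates are millimetres in an axis-aligned frame whose
origin sits at the grid corner: the centre of voxel ``(i, j, k)`` lies at
``origin + ((i, j, k) + 0.5) * spacing``.  Axes 0 and 1 are the in-plane
(coronal) axes; axis 2 is the through-plane (slice) axis, so a coronal
slice is ``voxels[:, :, k]``.  Every module in the package shares this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageVolume", "SegmentationMask", "SeedPointSet", "voxel_centers"]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive mm values, got {spacing}")
    return spacing


@dataclass
class ImageVolume:
    """A 3D scalar grid with anisotropic voxel spacing (mm) and origin."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError(f"volume must be a nonempty 3D grid, got shape {self.voxels.shape}")
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of every voxel centre, shape (n_voxels, 3)."""
        return voxel_centers(self.shape, self.spacing, self.origin)


@dataclass
class SegmentationMask:
    """A binary grid co-registered with an :class:`ImageVolume`.

    A bowel-wall mask covers the wall only, outer serosa to inner mucosa;
    the lumen and its contents are excluded by construction.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError(f"mask must be a nonempty 3D grid, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask voxels must be binary (0/1)")
            arr = arr.astype(bool)
        self.voxels = arr
        self.spacing = _check_spacing(self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(self.voxels.sum())

    def voxel_centers(self) -> np.ndarray:
        return voxel_centers(self.shape, self.spacing, self.origin)

    def assert_coregistered(self, other: "ImageVolume | SegmentationMask") -> None:
        if self.shape != other.shape or not np.allclose(self.spacing, other.spacing) \
                or not np.allclose(self.origin, other.origin):
            raise ValueError(
                "grids are not co-registered: "
                f"{self.shape}@{self.spacing} vs {other.shape}@{other.spacing}"
            )


@dataclass
class SeedPointSet:
    """Ordered operator seed points (physical mm) placed along the lumen."""

    points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(f"seed points must be an (n, 3) array, got shape {pts.shape}")
        if pts.shape[0] < 2:
            raise ValueError("at least 2 seed points are required to build a centerline")
        if not np.all(np.isfinite(pts)):
            raise ValueError("seed points must be finite (no NaN/inf coordinates)")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]


def voxel_centers(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Physical centres of all voxels on a grid, shape (n_voxels, 3), C order."""
    axes = [
        (np.arange(n) + 0.5) * s + o
        for n, s, o in zip(shape, spacing, origin)
    ]
    grid = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grid], axis=1)
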