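"""Bowel-wall segmentation: manual-mask validation and the semi-automated
centerline-guided partition-and-score pipeline.

The semi-automated route mirrors the workflow of centerline-guided bowel
segmentation tools: within a region of interest around the operator's
centerline, k-means clustering over intensity and spatially weighted
coordinates splits the image into superpixel-like partitions (each split
into face-connected components so partitions are contiguous); each
partition is summarized by a feature vector (intensity statistics,
geometry, and centerline-relative position); a random-forest regressor
scores the probability that the partition belongs to the bowel wall; and
the final mask is assembled from high-probability partitions, with a hard
geometric lumen exclusion and a connectivity filter to the wall band.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestRegressor

from .centerline import Centerline
from .image import ImageVolume, SegmentationMask

__all__ = [
    "SemiAutoConfig", "PartitionMap", "PartitionModel",
    "validate_manual_mask", "partition_image", "extract_features",
    "wall_fraction_targets", "train_partition_model",
    "assemble_segmentation", "segment_semiauto", "dice_coefficient",
    "FEATURE_NAMES",
]

FEATURE_NAMES = (
    "mean_intensity",
    "sd_intensity",
    "voxel_count",
    "volume_mm3",
    "min_dist_centerline_mm",
    "mean_dist_centerline_mm",
    "elongation",
    "boundary_gradient",
    "wall_band_fraction",
)

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass
class SemiAutoConfig:
    """Tunable parameters of the semi-automated segmenter.

    ``k`` and ``spatial_weight`` set the superpixel granularity (SLIC-like
    compactness trade-off); ``lumen_radius_mm`` and ``wall_band_mm`` define
    the geometric lumen exclusion and the annular band where wall tissue is
    expected; ``threshold`` is the inclusion-probability cut (>= includes).
    """

    k: int = 40
    spatial_weight: float = 0.5
    roi_radius_mm: float = 20.0
    lumen_radius_mm: float = 5.0
    wall_band_mm: float = 6.0
    threshold: float = 0.5
    n_trees: int = 200
    seed: int = 0


@dataclass
class PartitionMap:
    """Contiguous partitions of the ROI: 0 = outside, 1..n = partitions."""

    labels: np.ndarray
    n_partitions: int
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    dist_to_centerline_mm: np.ndarray  # same grid, inf outside ROI

    def __post_init__(self) -> None:
        assert self.labels.shape == self.dist_to_centerline_mm.shape

    def assert_contiguous(self) -> None:
        """Every nonzero label must form one face-connected component."""
        for lab in range(1, self.n_partitions + 1):
            _, n = ndimage.label(self.labels == lab, structure=_FACE_STRUCTURE)
            if n != 1:
                raise AssertionError(f"partition {lab} has {n} face-connected components")


def distance_to_centerline(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float],
    cl: Centerline,
) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) from voxel centre to the centerline."""
    centers = np.stack(np.meshgrid(
        *[(np.arange(n) + 0.5) * s + o for n, s, o in zip(shape, spacing, origin)],
        indexing="ij",
    ), axis=-1).reshape(-1, 3)
    dist, _ = cKDTree(cl.points).query(centers)
    return dist.reshape(shape)


def validate_manual_mask(
    mask: SegmentationMask,
    volume: ImageVolume,
    cl: Centerline,
    lumen_radius_mm: float = 5.0,
    band_mm: float = 20.0,
    lumen_tolerance: float = 0.01,
    band_tolerance: float = 0.05,
) -> SegmentationMask:
    """Check wall-only topology of a manual mask and return a cleaned copy.

    The mask must exclude the lumen (voxels within ``lumen_radius_mm`` of
    the centerline) and stay within ``band_mm`` of the centerline.  Small
    violations (fractions below the tolerances) are stripped; larger ones
    raise, since a wall mask must exclude the bowel lumen and intraluminal
    contents by definition.
    """
    mask.assert_coregistered(volume)
    n = mask.count()
    if n == 0:
        raise ValueError("manual mask is empty")
    dist = distance_to_centerline(mask.shape, mask.spacing, mask.origin, cl)
    in_lumen = mask.voxels & (dist < lumen_radius_mm)
    frac_lumen = in_lumen.sum() / n
    if frac_lumen > lumen_tolerance:
        raise ValueError(
            f"manual mask overlaps the lumen band in {in_lumen.sum()} voxels "
            f"({100 * frac_lumen:.1f}%): the wall mask must exclude the bowel "
            "lumen, including intraluminal contents"
        )
    out_band = mask.voxels & (dist > band_mm)
    frac_out = out_band.sum() / n
    if frac_out > band_tolerance:
        raise ValueError(
            f"manual mask extends beyond the {band_mm} mm centerline band in "
            f"{out_band.sum()} voxels ({100 * frac_out:.1f}%)"
        )
    cleaned = mask.voxels & ~in_lumen & ~out_band
    if in_lumen.any() or out_band.any():
        warnings.warn(
            f"stripped {int(in_lumen.sum())} lumen and {int(out_band.sum())} "
            "out-of-band voxel(s) from manual mask",
            stacklevel=2,
        )
    return SegmentationMask(voxels=cleaned, spacing=mask.spacing, origin=mask.origin)


def partition_image(
    volume: ImageVolume,
    cl: Centerline,
    k: int = 40,
    roi_radius_mm: float = 20.0,
    spatial_weight: float = 0.5,
    seed: int = 0,
) -> PartitionMap:
    """Split the centerline neighbourhood into contiguous partitions.

    K-means clusters voxels of the ROI (all voxels within ``roi_radius_mm``
    of the centerline) in a feature space of standardized intensity plus
    spatially weighted physical coordinates; every cluster is then split
    into face-connected components, so each returned partition is
    contiguous.  Deterministic for a fixed ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if spatial_weight < 0:
        raise ValueError("spatial_weight must be nonnegative")
    dist = distance_to_centerline(volume.shape, volume.spacing, volume.origin, cl)
    roi = dist <= roi_radius_mm
    n_roi = int(roi.sum())
    if n_roi == 0:
        raise ValueError("ROI around the centerline is empty")
    if k > n_roi:
        raise ValueError(f"k={k} exceeds the {n_roi} voxels in the ROI")

    intensity = volume.voxels[roi].astype(float)
    sd = intensity.std()
    feat_int = (intensity - intensity.mean()) / (sd if sd > 0 else 1.0)
    coords = np.argwhere(roi) * np.asarray(volume.spacing)  # mm, origin-free
    # typical partition pitch: equal share of the ROI volume per cluster
    pitch = (n_roi * volume.voxel_volume_mm3 / k) ** (1.0 / 3.0)
    feats = np.column_stack([feat_int, spatial_weight * coords / pitch])

    km = KMeans(n_clusters=k, random_state=seed, n_init=3)
    clusters = km.fit_predict(feats)

    labels = np.zeros(volume.shape, dtype=np.int32)
    next_label = 1
    cluster_grid = np.full(volume.shape, -1, dtype=np.int32)
    cluster_grid[roi] = clusters
    for c in range(k):
        comp, n_comp = ndimage.label(cluster_grid == c, structure=_FACE_STRUCTURE)
        for j in range(1, n_comp + 1):
            labels[comp == j] = next_label
            next_label += 1
    dist_out = np.where(roi, dist, np.inf)
    return PartitionMap(
        labels=labels,
        n_partitions=next_label - 1,
        spacing=volume.spacing,
        origin=volume.origin,
        dist_to_centerline_mm=dist_out,
    )


def _boundary_mask(labels: np.ndarray) -> np.ndarray:
    """Voxels with at least one face neighbour carrying a different label."""
    boundary = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(0, -1)
        sl_b[ax] = slice(1, None)
        diff = labels[tuple(sl_a)] != labels[tuple(sl_b)]
        boundary[tuple(sl_a)] |= diff
        boundary[tuple(sl_b)] |= diff
    # grid edges are boundaries too
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        boundary[tuple(sl)] = True
        sl[ax] = -1
        boundary[tuple(sl)] = True
    return boundary


def extract_features(
    pm: PartitionMap,
    volume: ImageVolume,
    cl: Centerline,
    lumen_radius_mm: float = 5.0,
    wall_band_mm: float = 6.0,
) -> pd.DataFrame:
    """One feature row per partition (see :data:`FEATURE_NAMES`).

    Distances are physical mm; the wall-band fraction is the share of the
    partition lying in the annulus ``[lumen_radius, lumen_radius +
    wall_band]`` around the centerline, where wall tissue is expected.
    """
    if pm.labels.shape != volume.shape:
        raise ValueError("partition map and volume are not co-registered")
    labels = pm.labels
    inside = labels > 0
    lab = labels[inside]
    assert lab.min() >= 1
    intensity = volume.voxels[inside].astype(float)
    dist = pm.dist_to_centerline_mm[inside]
    coords = np.argwhere(inside) * np.asarray(volume.spacing)

    n = pm.n_partitions
    counts = np.bincount(lab, minlength=n + 1)[1:]
    assert counts.min() >= 1, "empty partition label"
    sums = np.bincount(lab, weights=intensity, minlength=n + 1)[1:]
    mean_int = sums / counts
    sq = np.bincount(lab, weights=intensity ** 2, minlength=n + 1)[1:]
    var = np.maximum(sq / counts - mean_int ** 2, 0.0)
    sd_int = np.sqrt(var)

    min_dist = np.full(n, np.inf)
    np.minimum.at(min_dist, lab - 1, dist)
    mean_dist = np.bincount(lab, weights=dist, minlength=n + 1)[1:] / counts

    in_band = (dist >= lumen_radius_mm) & (dist <= lumen_radius_mm + wall_band_mm)
    band_frac = np.bincount(lab, weights=in_band.astype(float), minlength=n + 1)[1:] / counts

    # elongation: ratio of largest to smallest principal axis length (mm)
    elong = np.ones(n)
    order = np.argsort(lab, kind="stable")
    sorted_lab = lab[order]
    sorted_coords = coords[order]
    starts = np.searchsorted(sorted_lab, np.arange(1, n + 2))
    floor_var = (min(volume.spacing) / 2.0) ** 2
    for p in range(n):
        c = sorted_coords[starts[p]:starts[p + 1]]
        if len(c) < 2:
            continue
        cov = np.cov(c, rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(cov))
        elong[p] = np.sqrt(max(eig[-1], floor_var) / max(eig[0], floor_var))

    grad = np.gradient(volume.voxels.astype(float), *volume.spacing)
    gradmag = np.sqrt(sum(g ** 2 for g in grad))
    boundary = _boundary_mask(labels) & inside
    blab = labels[boundary]
    bcounts = np.bincount(blab, minlength=n + 1)[1:]
    bsums = np.bincount(blab, weights=gradmag[boundary], minlength=n + 1)[1:]
    boundary_grad = np.divide(bsums, bcounts, out=np.zeros(n), where=bcounts > 0)

    df = pd.DataFrame({
        "label": np.arange(1, n + 1),
        "mean_intensity": mean_int,
        "sd_intensity": sd_int,
        "voxel_count": counts.astype(float),
        "volume_mm3": counts * float(np.prod(pm.spacing)),
        "min_dist_centerline_mm": min_dist,
        "mean_dist_centerline_mm": mean_dist,
        "elongation": elong,
        "boundary_gradient": boundary_grad,
        "wall_band_fraction": band_frac,
    })
    if not np.all(np.isfinite(df[list(FEATURE_NAMES)].to_numpy())):
        raise AssertionError("non-finite feature value")
    return df


def wall_fraction_targets(pm: PartitionMap, truth_wall: SegmentationMask) -> np.ndarray:
    """Soft training targets: fraction of each partition inside the true wall."""
    lab = pm.labels[pm.labels > 0]
    inside_truth = truth_wall.voxels[pm.labels > 0].astype(float)
    n = pm.n_partitions
    counts = np.bincount(lab, minlength=n + 1)[1:]
    hits = np.bincount(lab, weights=inside_truth, minlength=n + 1)[1:]
    return hits / counts


def _schema_hash(feature_names: tuple[str, ...]) -> str:
    return hashlib.sha256(",".join(feature_names).encode()).hexdigest()[:16]


@dataclass
class PartitionModel:
    """A fitted random-forest partition scorer with schema metadata."""

    regressor: RandomForestRegressor
    feature_names: tuple[str, ...] = FEATURE_NAMES
    schema_hash: str = ""
    seed: int = 0
    n_trees: int = 200
    version: str = "1"
    training_n_partitions: int = 0

    def __post_init__(self) -> None:
        if not self.schema_hash:
            self.schema_hash = _schema_hash(self.feature_names)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Inclusion probability per partition, clipped to [0, 1]."""
        missing = set(self.feature_names) - set(features.columns)
        if missing or _schema_hash(tuple(self.feature_names)) != self.schema_hash:
            raise ValueError(f"feature schema mismatch; missing columns {sorted(missing)}")
        X = features[list(self.feature_names)].to_numpy()
        return np.clip(self.regressor.predict(X), 0.0, 1.0)

    def save(self, path) -> None:
        import joblib
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "PartitionModel":
        import joblib
        model = joblib.load(path)
        if not isinstance(model, PartitionModel):
            raise ValueError("file does not contain a PartitionModel")
        return model


def train_partition_model(
    examples: list[tuple[pd.DataFrame, np.ndarray]],
    n_trees: int = 200,
    seed: int = 0,
    **forest_kwargs,
) -> PartitionModel:
    """Fit the partition scorer on (feature table, wall-fraction target) pairs."""
    if len(examples) < 1:
        raise ValueError("need at least one training example")
    for feats, _ in examples:
        missing = set(FEATURE_NAMES) - set(feats.columns)
        if missing:
            raise ValueError(f"feature schema mismatch across tables: missing {sorted(missing)}")
    X = np.concatenate([f[list(FEATURE_NAMES)].to_numpy() for f, _ in examples])
    y = np.concatenate([np.asarray(t, dtype=float) for _, t in examples])
    if len(X) != len(y):
        raise ValueError("feature rows and targets differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("training targets must contain at least 2 distinct values")
    rf = RandomForestRegressor(n_estimators=n_trees, random_state=seed, **forest_kwargs)
    rf.fit(X, y)
    return PartitionModel(
        regressor=rf, seed=seed, n_trees=n_trees, training_n_partitions=len(y)
    )


def assemble_segmentation(
    pm: PartitionMap,
    probabilities: np.ndarray | pd.DataFrame,
    threshold: float,
    cl: Centerline,
    lumen_radius_mm: float = 5.0,
    wall_band_mm: float = 6.0,
) -> SegmentationMask:
    """Union of partitions with inclusion probability >= threshold.

    Voxels inside the geometric lumen band are removed unconditionally, and
    only face-connected components that touch the wall-band annulus around
    the centerline are retained.  An empty result is a valid output (a
    segment may genuinely contain no wall above threshold) and triggers a
    warning, not an error.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if isinstance(probabilities, pd.DataFrame):
        if "inclusion_probability" not in probabilities.columns:
            raise ValueError("feature table lacks an inclusion_probability column")
        probs = probabilities["inclusion_probability"].to_numpy()
    else:
        probs = np.asarray(probabilities, dtype=float)
    if probs.shape != (pm.n_partitions,):
        raise ValueError("need one probability per partition")

    selected = np.flatnonzero(probs >= threshold) + 1
    mask = np.isin(pm.labels, selected)
    mask &= ~(pm.dist_to_centerline_mm < lumen_radius_mm)  # hard lumen exclusion

    if mask.any():
        comp, n_comp = ndimage.label(mask, structure=_FACE_STRUCTURE)
        band = (pm.dist_to_centerline_mm >= lumen_radius_mm) \
            & (pm.dist_to_centerline_mm <= lumen_radius_mm + wall_band_mm)
        keep = np.unique(comp[band & mask])
        keep = keep[keep > 0]
        mask = np.isin(comp, keep)
    if not mask.any():
        warnings.warn("assembled segmentation is empty", stacklevel=2)
    return SegmentationMask(voxels=mask, spacing=pm.spacing, origin=pm.origin)


def segment_semiauto(
    volume: ImageVolume,
    cl: Centerline,
    model: PartitionModel,
    config: SemiAutoConfig | None = None,
) -> tuple[SegmentationMask, pd.DataFrame]:
    """Full semi-automated pipeline: partition, score, assemble.

    Returns the wall mask and the partition feature table with the
    ``inclusion_probability`` column appended.
    """
    cfg = config or SemiAutoConfig()
    pm = partition_image(
        volume, cl, k=cfg.k, roi_radius_mm=cfg.roi_radius_mm,
        spatial_weight=cfg.spatial_weight, seed=cfg.seed,
    )
    feats = extract_features(
        pm, volume, cl,
        lumen_radius_mm=cfg.lumen_radius_mm, wall_band_mm=cfg.wall_band_mm,
    )
    feats = feats.assign(inclusion_probability=model.predict(feats))
    mask = assemble_segmentation(
        pm, feats, cfg.threshold, cl,
        lumen_radius_mm=cfg.lumen_radius_mm, wall_band_mm=cfg.wall_band_mm,
    )
    return mask, feats


def dice_coefficient(a: SegmentationMask, b: SegmentationMask) -> float:
    """Overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a.assert_coregistered(b)
    na, nb = a.count(), b.count()
    if na + nb == 0:
        return 1.0
    inter = int((a.voxels & b.voxels).sum())
    return 2.0 * inter / (na + nb)
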