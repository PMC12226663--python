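"""File I/O: NIfTI volumes and masks, seed-point lists, measurement tables.

NIfTI-1 is the single volume/mask format (spacing carried in the header
zooms, origin in the affine translation).  Seed points travel as JSON
(``{"points_mm": [[x, y, z], ...]}``) or CSV with columns x_mm, y_mm, z_mm.
Longitudinal measurement tables are CSV in long format, one row per
(subject, timepoint); missing measurements are empty cells, never zeros.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .image import ImageVolume, SegmentationMask, SeedPointSet
from .phantom import MEASUREMENTS, TIMEPOINTS

__all__ = [
    "read_volume", "write_volume", "read_mask", "write_mask",
    "read_seeds", "write_seeds", "read_table", "write_table",
    "write_report", "validate_table",
]

TABLE_COLUMNS = ["subject_id", "timepoint", *MEASUREMENTS]


def _affine(spacing, origin) -> np.ndarray:
    aff = np.diag([*spacing, 1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(vol: ImageVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.voxels), _affine(vol.spacing, vol.origin))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # corrupt header, wrong magic, ...
        raise ValueError(f"could not read {path} as NIfTI-1: {exc}") from exc
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got {data.ndim}D data")
    # NIfTI-1 stores zooms/affine as float32; round to sub-nanometre so
    # mm-scale spacings (e.g. 1.3) round-trip exactly.
    spacing = tuple(round(float(z), 6) for z in img.header.get_zooms()[:3])
    origin = tuple(round(float(x), 6) for x in img.affine[:3, 3])
    return ImageVolume(voxels=data, spacing=spacing, origin=origin)


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing, mask.origin))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> SegmentationMask:
    vol = read_volume(path)
    return SegmentationMask(voxels=vol.voxels != 0, spacing=vol.spacing, origin=vol.origin)


def write_seeds(seeds: SeedPointSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(seeds.points, columns=["x_mm", "y_mm", "z_mm"]).to_csv(path, index=False)
    else:
        path.write_text(json.dumps({"points_mm": seeds.points.tolist()}, indent=1))


def read_seeds(path: str | Path) -> SeedPointSet:
    """Read an ordered seed list; order is preserved exactly as given."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such seed file: {path}")
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = {"x_mm", "y_mm", "z_mm"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: seed CSV lacks columns {sorted(missing)}")
        pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)
    else:
        payload = json.loads(path.read_text())
        if "points_mm" not in payload:
            raise ValueError(f"{path}: seed JSON must contain 'points_mm'")
        pts = np.asarray(payload["points_mm"], dtype=float)
    return SeedPointSet(points=pts)  # validates count and finiteness


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a longitudinal measurement table's schema and invariants."""
    missing = {"subject_id", "timepoint"} - set(df.columns)
    if missing:
        raise ValueError(f"table lacks required columns {sorted(missing)}")
    bad_tp = set(df["timepoint"].unique()) - set(TIMEPOINTS)
    if bad_tp:
        raise ValueError(f"unknown timepoints {sorted(bad_tp)}; expected {TIMEPOINTS}")
    dup = df.duplicated(subset=["subject_id", "timepoint"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "timepoint"]].to_records(index=False).tolist()
        raise ValueError(f"duplicate (subject, timepoint) rows: {pairs}")
    for m in MEASUREMENTS:
        if m in df.columns:
            vals = pd.to_numeric(df[m], errors="coerce")
            if (vals.dropna() < 0).any():
                raise ValueError(f"{m}: measurements must be nonnegative")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    validate_table(df)
    cols = [c for c in TABLE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, na_rep="")


def read_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_table(df)


def write_report(table: pd.DataFrame, stats_results, out_dir: str | Path) -> dict[str, Path]:
    """Write the measurement records plus the statistics bundle as CSVs.

    ``stats_results`` is a :class:`~enterometry.stats.StudyResults` (or any
    object exposing the same frames).  Returns the paths written, keyed by
    report name.  Column order is deterministic.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    records = out_dir / "records.csv"
    if len(table):
        write_table(table, records)
    else:  # header-only file for an empty cohort
        validate_table(table) if set(table.columns) >= {"subject_id", "timepoint"} else None
        pd.DataFrame(columns=TABLE_COLUMNS).to_csv(records, index=False)
    paths["records"] = records

    if stats_results is not None:
        frames = {
            "change_tests": stats_results.change_tests,
            "percent_changes": stats_results.percent_changes,
            "correlations": stats_results.correlations_long,
        }
        for name, frame in frames.items():
            p = out_dir / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = p
        a = stats_results.agreement
        p = out_dir / "agreement.csv"
        pd.DataFrame([{
            "comparison": "manual_vs_semiauto_volume",
            "icc": a.icc_estimate, "ci_low": a.ci_low, "ci_high": a.ci_high,
            "band": a.band, "n_pairs": a.n_pairs,
        }]).to_csv(p, index=False)
        paths["agreement"] = p
    return paths
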