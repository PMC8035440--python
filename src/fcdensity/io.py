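"""NIfTI, motion-file and manifest I/O."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import BoldRun, GridGeometry, MotionParams, TissueMasks

logger = logging.getLogger(__name__)

__all__ = [
    "read_bold",
    "write_bold",
    "read_mask",
    "write_map",
    "read_masks",
    "write_masks",
    "read_motion",
    "write_motion",
    "read_manifest",
    "write_manifest",
]


def read_bold(path: str | Path, tr_s: float | None = None) -> BoldRun:
    """Load a 4D BOLD NIfTI file.

    TR is taken from the header's time zoom unless overridden.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD volume, got {data.ndim}D")
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    geometry = GridGeometry(dims=data.shape[:3], affine=img.affine)
    return BoldRun(data=data.astype(np.float64), geometry=geometry, tr_s=tr_s)


def write_bold(run: BoldRun, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(run.data.astype(np.float32), run.geometry.affine)
    img.header.set_zooms(run.geometry.voxel_size_mm + (run.tr_s,))
    img.to_filename(str(path))
    return path


def write_map(values: np.ndarray, geometry: GridGeometry, path: str | Path) -> Path:
    """Write a 3D scalar map (float32) on the given grid."""
    values = np.asarray(values)
    if values.ndim != 3:
        raise ValueError(f"expected a 3D map, got {values.ndim}D")
    path = Path(path)
    nib.Nifti1Image(values.astype(np.float32), geometry.affine).to_filename(str(path))
    return path


def read_mask(path: str | Path, geometry: GridGeometry | None = None) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got {data.ndim}D")
    if geometry is not None and data.shape != geometry.dims:
        raise ValueError(
            f"{path}: mask shape {data.shape} does not match grid {geometry.dims}"
        )
    return data > 0


_MASK_NAMES = ("gray", "white", "csf", "whole_brain")


def write_masks(masks: TissueMasks, geometry: GridGeometry, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in _MASK_NAMES:
        arr = getattr(masks, name).astype(np.uint8)
        p = out_dir / f"mask_{name}.nii.gz"
        nib.Nifti1Image(arr, geometry.affine).to_filename(str(p))
        paths[name] = p
    return paths


def read_masks(mask_dir: str | Path, geometry: GridGeometry | None = None) -> TissueMasks:
    mask_dir = Path(mask_dir)
    arrays = {
        name: read_mask(mask_dir / f"mask_{name}.nii.gz", geometry)
        for name in _MASK_NAMES
    }
    return TissueMasks(geometry=geometry, **arrays)


def read_motion(path: str | Path, expected_rows: int | None = None) -> MotionParams:
    """Parse a whitespace-delimited 6-column motion file.

    Columns beyond the sixth are ignored with a note; non-numeric input is
    reported with its line number; a row count disagreeing with the BOLD
    run is an error.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 columns, got {len(fields)}"
                )
            try:
                rows.append([float(x) for x in fields[:6]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
            if len(fields) > 6 and lineno == 1:
                logger.info("%s: ignoring %d extra trailing columns",
                            path, len(fields) - 6)
    if not rows:
        raise ValueError(f"{path}: empty motion file")
    mat = np.array(rows)
    if expected_rows is not None and mat.shape[0] != expected_rows:
        raise ValueError(
            f"{path}: {mat.shape[0]} motion rows but {expected_rows} volumes"
        )
    return MotionParams.from_matrix(mat)


def write_motion(motion: MotionParams, path: str | Path) -> Path:
    path = Path(path)
    np.savetxt(path, motion.as_matrix(), fmt="%.6f")
    return path


def write_manifest(records: list[dict], path: str | Path) -> Path:
    """Cohort manifest TSV: subject_id, group, bold/motion paths."""
    path = Path(path)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str})
    required = {"subject_id", "group", "bold_path", "motion_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df
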