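"""File formats: NIfTI volumes/masks, cohort CSV, result JSON.

HU volumes are written as signed 16-bit integers with voxel spacing in
the NIfTI header (values are rounded to the nearest integer at write
time; in-memory pipelines keep float64 precision). Masks are 0/1/2
uint8 NIfTI. Cohort tables round-trip through CSV with full float
precision and explicit missingness (empty cells).

Input volumes are assumed already calibrated to HU; no rescale-slope
handling beyond what the NIfTI format itself mandates is applied.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Dict, Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .densitometry import (
    AlignmentError,
    DensitometryResult,
    DensityVolume,
    LungMask,
    Phase,
)
from .cohort import validate_cohort

__all__ = [
    "FormatError",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "write_result",
    "read_result",
    "read_cohort",
    "write_cohort",
]


class FormatError(ValueError):
    """Raised when an input file cannot be interpreted."""


def _load_nifti(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    try:
        img = nib.load(str(path))
    except Exception as err:  # nibabel raises several unrelated types
        raise FormatError(f"{path}: not a readable NIfTI file ({err})") from err
    if len(img.shape) != 3:
        raise FormatError(f"{path}: expected a 3-D image, got shape {img.shape}")
    return img


def read_volume(path: str | Path, phase: Phase | str = Phase.INSPIRATORY) -> DensityVolume:
    """Load an HU volume from NIfTI; spacing comes from the header zooms."""
    img = _load_nifti(path)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel spacing {zooms} in header")
    return DensityVolume(
        np.asarray(img.dataobj, dtype=np.float64), tuple(float(z) for z in zooms), phase
    )


def write_volume(
    volume: DensityVolume, path: str | Path, dtype: np.dtype | type = np.int16
) -> None:
    """Write a volume as NIfTI; integer dtypes round HU to the nearest unit."""
    values = volume.values
    if np.issubdtype(np.dtype(dtype), np.integer):
        values = np.rint(values)
    affine = np.diag([*volume.spacing, 1.0])
    img = nib.Nifti1Image(values.astype(dtype), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path, volume: Optional[DensityVolume] = None) -> LungMask:
    """Load a 0/1/2 lung mask; optionally check alignment with a volume."""
    img = _load_nifti(path)
    arr = np.asarray(img.dataobj)
    if not np.isin(arr, (0, 1, 2)).all():
        raise FormatError(f"{path}: mask voxels must be 0, 1 or 2")
    mask = LungMask(arr.astype(np.uint8))
    if volume is not None and mask.shape != volume.shape:
        raise AlignmentError(
            f"{path}: mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    return mask


def write_mask(mask: LungMask, path: str | Path, spacing=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), affine)
    img.header.set_zooms(tuple(float(s) for s in spacing))
    nib.save(img, str(path))


def _result_to_jsonable(result: DensitometryResult) -> Dict[str, Any]:
    d = dataclasses.asdict(result)
    for key in ("laa_pct", "haa_pct"):
        d[key] = {str(t): v for t, v in d[key].items()}
        if d.get("per_side"):
            for side in d["per_side"].values():
                side[key] = {str(t): v for t, v in side[key].items()}
    return d


def write_result(
    result: DensitometryResult,
    path: str | Path,
    provenance: Optional[Dict[str, Any]] = None,
) -> None:
    """Write a per-subject result JSON with an embedded provenance block."""
    payload = {"indices": _result_to_jsonable(result), "provenance": provenance or {}}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_result(path: str | Path) -> Dict[str, Any]:
    try:
        return json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"{path}: invalid result JSON ({err})") from err


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load a cohort CSV; empty cells become NaN (field absent)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: file does not exist")
    try:
        table = pd.read_csv(path)
    except Exception as err:
        raise FormatError(f"{path}: unreadable cohort CSV ({err})") from err
    try:
        validate_cohort(table)
    except ValueError as err:
        raise FormatError(f"{path}: {err}") from err
    return table


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.10g")
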