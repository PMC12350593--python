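"""NIfTI volume and cohort CSV input/output."""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .fractal import BinaryOccupancy
from .intensity import IntensityVolume, SEQUENCE_LABELS

logger = logging.getLogger(__name__)

_SUFFIX_LABELS = {"_t1": "T1", "_t1c": "T1c", "_t2": "T2", "_flair": "FLAIR"}

AFFINE_TOLERANCE = 1e-4


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, ...], np.ndarray]:
    """Read a NIfTI-1 volume; returns (grid, per-axis spacing in mm, affine)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several types
        raise ValidationError(f"cannot read NIfTI file {path}: {exc}") from exc
    grid = np.asarray(img.get_fdata())
    spacing = tuple(float(z) for z in img.header.get_zooms()[: grid.ndim])
    return grid, spacing, np.asarray(img.affine)


def read_mask(path: str | Path) -> BinaryOccupancy:
    """Read a binary segmentation mask; files with >2 distinct values are rejected."""
    grid, spacing, _ = read_volume(path)
    values = np.unique(grid)
    if len(values) > 2 or (len(values) == 2 and values[0] != 0):
        raise ValidationError(
            f"mask {path} is not binary: distinct values {values[:5].tolist()}"
        )
    return BinaryOccupancy(grid != 0, spacing=spacing)


def infer_sequence_label(path: str | Path) -> str:
    """Sequence label from filename suffix convention (_t1, _t1c, _t2, _flair)."""
    stem = Path(path).name.lower()
    for ext in (".nii.gz", ".nii"):
        if stem.endswith(ext):
            stem = stem[: -len(ext)]
    for suffix, label in _SUFFIX_LABELS.items():
        if stem.endswith(suffix):
            return label
    return "other"


def read_intensity_pair(
    intensity_path: str | Path,
    mask_path: str | Path,
    sequence_label: str | None = None,
) -> IntensityVolume:
    """Read a co-registered intensity + mask NIfTI pair.

    Shapes must match and affines must agree within 1e-4; the sequence label
    is taken from the flag or inferred from the intensity filename suffix.
    """
    values, _, affine_v = read_volume(intensity_path)
    mask = read_mask(mask_path)
    _, _, affine_m = read_volume(mask_path)
    if values.shape != mask.cells.shape:
        raise ValidationError(
            f"pair mismatch: {intensity_path} has shape {values.shape}, "
            f"{mask_path} has shape {mask.cells.shape}"
        )
    if np.max(np.abs(affine_v - affine_m)) > AFFINE_TOLERANCE:
        raise ValidationError(
            f"pair mismatch: affines of {intensity_path} and {mask_path} "
            f"differ by more than {AFFINE_TOLERANCE}"
        )
    if sequence_label is None:
        sequence_label = infer_sequence_label(intensity_path)
    if sequence_label not in SEQUENCE_LABELS:
        raise ValidationError(f"unknown sequence label {sequence_label!r}")
    return IntensityVolume(values=values, mask=mask.cells, sequence_label=sequence_label)


def write_volume(
    grid: np.ndarray,
    path: str | Path,
    spacing: tuple[float, ...] | None = None,
) -> None:
    """Write a grid as NIfTI-1 with a diagonal affine from the spacing."""
    grid = np.asarray(grid)
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    affine = np.eye(4)
    if spacing is not None:
        for i, s in enumerate(spacing[:3]):
            affine[i, i] = s
    nib.save(nib.Nifti1Image(grid, affine), str(path))


def read_cohort_csv(
    path: str | Path,
    continuous: list[str],
    binary: list[str],
    label: str,
) -> pd.DataFrame:
    """Read and validate a per-patient cohort CSV.

    Required columns are the declared continuous/binary features and the
    label.  Rows with consistency label "miscellaneous" are retained in the
    returned frame but flagged (they are excluded from binary modeling by
    the caller); non-numeric continuous values and non-0/1 binary values
    raise with the offending row number.
    """
    path = Path(path)
    df = pd.read_csv(path)
    required = list(continuous) + list(binary) + [label]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort CSV {path} is missing column(s) {missing}")
    for col in continuous:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValidationError(
                f"non-numeric value in continuous column {col!r} at CSV line "
                f"{int(bad[0]) + 2}"
            )
        df[col] = coerced
    for col in binary:
        vals = set(pd.unique(df[col]))
        if not vals <= {0, 1, 0.0, 1.0}:
            bad = df.index[~df[col].isin([0, 1])][0]
            raise ValidationError(
                f"binary column {col!r} has non-0/1 value at CSV line {int(bad) + 2}"
            )
    if label in df.columns:
        n_misc = int((df[label] == "miscellaneous").sum())
        if n_misc:
            logger.warning(
                "%d row(s) with %r label 'miscellaneous' are excluded from binary modeling",
                n_misc,
                label,
            )
    return df
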