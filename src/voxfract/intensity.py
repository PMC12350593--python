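"""Lift a masked 3D intensity volume into a 4D binary surface for lacunarity.

In-mask voxel intensities are min-max quantized to L discrete levels and the
level becomes a fourth coordinate: voxel (x, y, z) with level l occupies the
single 4D cell (x, y, z, l).  The 4D occupancy therefore has exactly one
occupied cell per in-mask voxel, and its gliding-box lacunarity measures
joint spatial-and-intensity heterogeneity of the tumor texture.  Because the
4D position count is large, window positions are subsampled (default rate
0.01, i.e. 1:100).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import EmptyMaskError, ValidationError
from .fractal import (
    BinaryOccupancy,
    LacunarityConvention,
    LIResult,
    lacunarity_index,
    select_scales,
)

SEQUENCE_LABELS = ("T1", "T1c", "T2", "FLAIR", "other")

#: Default fraction of 4D window positions evaluated per scale.
DEFAULT_SUBSAMPLE_RATE = 0.01


@dataclass(frozen=True)
class IntensityVolume:
    """A 3D scalar volume with a co-registered binary mask and sequence label."""

    values: np.ndarray
    mask: np.ndarray
    sequence_label: str = "other"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            mask = mask != 0
        if values.ndim != 3:
            raise ValidationError(f"intensity volume must be 3-D, got {values.ndim}-D")
        if values.shape != mask.shape:
            raise ValidationError(
                f"intensity shape {values.shape} != mask shape {mask.shape}"
            )
        if self.sequence_label not in SEQUENCE_LABELS:
            raise ValidationError(
                f"sequence_label must be one of {SEQUENCE_LABELS}, got {self.sequence_label!r}"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class QuantizedVolume:
    """Integer intensity levels in [0, L-1] on mask cells; out-of-mask cells are ignored."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    vmin: float
    vmax: float


def quantize_intensities(vol: IntensityVolume, n_levels: int) -> QuantizedVolume:
    """Min-max quantization of in-mask intensities to ``n_levels`` integer levels.

    level(x) = rint((v(x) - vmin) / (vmax - vmin) * (L - 1)); a
    constant-intensity mask maps every cell to level 0.  The mapping is
    monotone and invariant to strictly increasing affine transforms of the
    intensities.
    """
    if n_levels < 2:
        raise ValidationError(f"n_levels must be >= 2, got {n_levels}")
    if not vol.mask.any():
        raise EmptyMaskError("intensity volume has an empty mask")
    in_mask = vol.values[vol.mask]
    vmin, vmax = float(in_mask.min()), float(in_mask.max())
    levels = np.zeros(vol.values.shape, dtype=np.int64)
    if vmax > vmin:
        scaled = (vol.values[vol.mask] - vmin) / (vmax - vmin) * (n_levels - 1)
        levels[vol.mask] = np.rint(scaled).astype(np.int64)
    return QuantizedVolume(
        levels=levels, mask=vol.mask, n_levels=int(n_levels), vmin=vmin, vmax=vmax
    )


def lift_to_4d(q: QuantizedVolume) -> BinaryOccupancy:
    """Embed the quantized volume as a 4D binary surface.

    Cell (x, y, z, l) is occupied iff (x, y, z) is in the mask and its level
    is l; the occupied-cell count equals the in-mask voxel count.
    """
    nx, ny, nz = q.mask.shape
    cells = np.zeros((nx, ny, nz, q.n_levels), dtype=bool)
    idx = np.nonzero(q.mask)
    cells[idx + (q.levels[idx],)] = True
    return BinaryOccupancy(cells)


def sequence_li(
    vol: IntensityVolume,
    scales: Sequence[int] | None = None,
    stride: int = 1,
    subsample_rate: float = DEFAULT_SUBSAMPLE_RATE,
    seed: int | None = None,
    n_levels: int | None = None,
    convention: LacunarityConvention = "one_plus_cv2",
) -> LIResult:
    """Lacunarity index of the 4D intensity surface of one MRI sequence.

    ``n_levels`` defaults to the largest spatial extent of the mask bounding
    box, so the intensity axis is geometrically commensurate with the
    spatial axes.  Window scales apply to all four axes, clipped per axis to
    the axis extent (the intensity axis can be shorter than the window).
    """
    if not vol.mask.any():
        raise EmptyMaskError("intensity volume has an empty mask")
    bbox = BinaryOccupancy(vol.mask).bounding_box()
    bbox_shape = tuple(sl.stop - sl.start for sl in bbox)
    if n_levels is None:
        n_levels = max(bbox_shape)
        n_levels = max(n_levels, 2)
    q = quantize_intensities(vol, n_levels)
    occ4 = lift_to_4d(q)
    if scales is None:
        scales = select_scales(occ4.cropped().shape)
    return lacunarity_index(
        occ4,
        scales,
        stride=stride,
        subsample_rate=subsample_rate,
        seed=seed,
        convention=convention,
        cap_window=True,
        label=vol.sequence_label,
    )
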