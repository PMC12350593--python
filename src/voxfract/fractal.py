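"""Box-counting fractal dimension and gliding-box lacunarity of n-D binary grids.

The two measurements share one substrate, :class:`BinaryOccupancy` — an
n-dimensional boolean grid (n = 3 for segmentation masks, n = 4 for
intensity-lifted volumes; see :mod:`voxfract.intensity`).

*Box counting* partitions the tight bounding box of the occupied cells into
non-overlapping ``scale``-sided boxes anchored at the bounding-box origin
(partial boxes at the far edges included) and counts boxes containing at
least one occupied cell.  The box-counting (Minkowski–Bouligand) dimension
FD is the slope of ln(box count) against ln(1/scale).

*Gliding-box lacunarity* slides a ``scale``-sided window over every position
where it fits entirely inside the bounding box (stride 1 by default),
records the occupied-cell mass in each window, and summarizes the mass
distribution as the Allain–Cloitre statistic

    Lambda(s) = 1 + (sigma / mu)^2

with population variance.  The lacunarity index LI is the slope of
ln Lambda(s) against ln(1/s) across scales.  Window positions may be
subsampled uniformly without replacement (seeded) to make high-dimensional
measurements tractable.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Literal, Sequence

import numpy as np

from .exceptions import (
    DegenerateWindowError,
    EmptyMaskError,
    InsufficientScalesError,
    ScaleSelectionError,
    ScaleTooLargeError,
    ValidationError,
)

logger = logging.getLogger(__name__)

LacunarityConvention = Literal["one_plus_cv2", "cv2"]

#: Relative spacing anisotropy above which a warning is emitted; the fractal
#: measures themselves always treat cells as isotropic.
ANISOTROPY_TOLERANCE = 0.05


@dataclass(frozen=True)
class BinaryOccupancy:
    """An n-D boolean grid of occupied cells (n >= 2).

    Parameters
    ----------
    cells
        Boolean array; nonzero entries of other dtypes are coerced to True.
    spacing
        Physical cell size per axis in mm.  Ignored by all dimension and
        lacunarity estimates (cells are treated as isotropic); a warning is
        emitted when anisotropy exceeds 5%.
    """

    cells: np.ndarray
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.cells)
        if arr.dtype != bool:
            arr = arr != 0
        object.__setattr__(self, "cells", arr)
        if arr.ndim < 2:
            raise ValidationError(f"occupancy must be at least 2-D, got {arr.ndim}-D")
        if any(s <= 0 for s in arr.shape):
            raise ValidationError(f"occupancy shape must be strictly positive, got {arr.shape}")
        if self.spacing is not None:
            sp = tuple(float(s) for s in self.spacing)
            if len(sp) != arr.ndim:
                raise ValidationError("spacing length must match dimensionality")
            if any(s <= 0 for s in sp):
                raise ValidationError("spacing must be strictly positive")
            if max(sp) / min(sp) - 1.0 > ANISOTROPY_TOLERANCE:
                warnings.warn(
                    f"voxel spacing anisotropy {max(sp) / min(sp) - 1.0:.1%} exceeds "
                    f"{ANISOTROPY_TOLERANCE:.0%}; fractal measures assume isotropic cells",
                    stacklevel=2,
                )
            object.__setattr__(self, "spacing", sp)

    @property
    def ndim(self) -> int:
        return self.cells.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.cells.shape

    @property
    def occupied_count(self) -> int:
        return int(np.count_nonzero(self.cells))

    def bounding_box(self) -> tuple[slice, ...]:
        """Tight bounding box of occupied cells as per-axis slices."""
        if not self.cells.any():
            raise EmptyMaskError("occupancy grid has no occupied cells")
        idx = np.nonzero(self.cells)
        return tuple(slice(int(ax.min()), int(ax.max()) + 1) for ax in idx)

    def cropped(self) -> np.ndarray:
        """Occupied-cell grid cropped to its tight bounding box."""
        return self.cells[self.bounding_box()]


@dataclass(frozen=True)
class ScaleSeries:
    """Ordered (scale, value) samples entering a log-log fit."""

    scales: tuple[int, ...]
    values: tuple[float, ...]
    kind: Literal["box_count", "lacunarity"]

    def __post_init__(self) -> None:
        if len(self.scales) != len(self.values):
            raise ValidationError("scales and values must have equal length")
        if any(s < 1 for s in self.scales):
            raise ValidationError("all scales must be >= 1")
        if any(b <= a for a, b in zip(self.scales, self.scales[1:])):
            raise ValidationError("scales must be strictly increasing")
        if self.kind == "box_count":
            if any(v <= 0 or v != int(v) for v in self.values):
                raise ValidationError("box counts must be positive integers")

    def __len__(self) -> int:
        return len(self.scales)


@dataclass(frozen=True)
class LogLogFit:
    """Ordinary least-squares fit of ln(value) against ln(1/scale)."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


@dataclass(frozen=True)
class FDResult:
    """Box-counting fractal dimension with its fit and per-scale counts."""

    fd: float
    fit: LogLogFit
    series: ScaleSeries


@dataclass(frozen=True)
class WindowMassStats:
    """Moments of the gliding-window mass distribution at one scale."""

    mean_mass: float
    variance: float
    n_windows_evaluated: int
    subsample_rate: float
    seed: int | None


@dataclass(frozen=True)
class LIResult:
    """Lacunarity index with its fit, per-scale values and mass statistics."""

    li: float
    fit: LogLogFit
    series: ScaleSeries
    per_scale_stats: tuple[WindowMassStats, ...]
    label: str | None = None


def select_scales(
    shape: Sequence[int], base: int = 2, min_count: int = 3
) -> list[int]:
    """Geometric scale grid {1, base, base^2, ...} for a grid of given shape.

    Scales run up to half the longest side.  For base 3 the full side is
    appended when it is an exact power of the base, so self-similar phantoms
    built on exact base-3 grids contribute their coarsest level.
    """
    if base not in (2, 3):
        raise ValidationError(f"base must be 2 or 3, got {base}")
    shape = tuple(int(s) for s in shape)
    if any(s <= 0 for s in shape):
        raise ValidationError("shape must be strictly positive")
    max_side = max(shape)
    limit = max_side // 2
    scales = []
    s = 1
    while s <= limit:
        scales.append(s)
        s *= base
    if base != 2:
        k = round(math.log(max_side, base))
        if base**k == max_side and max_side not in scales:
            scales.append(max_side)
    if len(scales) < min_count:
        axis = int(np.argmax(shape))
        raise ScaleSelectionError(
            f"only {len(scales)} admissible scales {scales} for shape {shape} "
            f"(limiting axis {axis}, extent {max_side}); {min_count} required"
        )
    return scales


def box_count(occ: BinaryOccupancy, scale: int) -> int:
    """Number of non-empty boxes in the scale-sided partition of the mask.

    Boxes are anchored at the minimum corner of the tight bounding box of
    occupied cells; partial boxes at the far edges are included.
    """
    scale = int(scale)
    if scale < 1:
        raise ValidationError(f"scale must be >= 1, got {scale}")
    sub = occ.cropped()
    if scale == 1:
        return int(np.count_nonzero(sub))
    pad = [(0, (-e) % scale) for e in sub.shape]
    padded = np.pad(sub, pad)
    new_shape = []
    for e in padded.shape:
        new_shape.extend((e // scale, scale))
    blocks = padded.reshape(new_shape)
    occupied = blocks.any(axis=tuple(range(1, 2 * sub.ndim, 2)))
    return int(np.count_nonzero(occupied))


def fit_loglog(series: ScaleSeries) -> LogLogFit:
    """OLS of ln(value) on ln(1/scale); natural log on both axes.

    When all values are equal the slope is exactly 0 and r^2 is reported as
    1 by convention (a constant series is a perfect flat line).
    """
    if len(series) < 3:
        raise ValidationError(f"log-log fit needs >= 3 points, got {len(series)}")
    values = np.asarray(series.values, dtype=float)
    if np.any(values <= 0):
        raise ValidationError("log-log fit requires strictly positive values")
    x = -np.log(np.asarray(series.scales, dtype=float))
    y = np.log(values)
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = float(((y - ym) ** 2).sum())
    if ss_tot == 0.0:
        return LogLogFit(slope=0.0, intercept=float(ym), r_squared=1.0, n_points=len(series))
    resid = y - (slope * x + intercept)
    r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return LogLogFit(
        slope=slope,
        intercept=intercept,
        r_squared=float(min(max(r2, 0.0), 1.0)),
        n_points=len(series),
    )


def fractal_dimension(
    occ: BinaryOccupancy,
    scales: Sequence[int] | None = None,
    base: int = 2,
) -> FDResult:
    """Box-counting fractal dimension over the given (or auto-selected) scales."""
    if scales is None:
        bbox_shape = occ.cropped().shape
        scales = select_scales(bbox_shape, base=base)
    scales = sorted(int(s) for s in scales)
    if len(scales) < 3:
        raise ValidationError("fractal dimension needs >= 3 scales")
    counts = [box_count(occ, s) for s in scales]
    series = ScaleSeries(tuple(scales), tuple(float(c) for c in counts), kind="box_count")
    fit = fit_loglog(series)
    fd = fit.slope
    if not (-0.05 <= fd <= occ.ndim + 0.05):
        warnings.warn(
            f"estimated dimension {fd:.3f} outside [0, {occ.ndim}] beyond fit tolerance",
            stacklevel=2,
        )
    return FDResult(fd=fd, fit=fit, series=series)


def _prefix_sums(sub: np.ndarray) -> np.ndarray:
    """Zero-padded n-D cumulative sums (summed-area table) of a boolean grid."""
    c = sub.astype(np.int64)
    for ax in range(sub.ndim):
        c = np.cumsum(c, axis=ax)
    return np.pad(c, [(1, 0)] * sub.ndim)


def _all_window_sums(
    sub: np.ndarray, win: tuple[int, ...], stride: int
) -> np.ndarray:
    """Masses of every stride-spaced window, via inclusion-exclusion on prefix sums."""
    S = _prefix_sums(sub)
    d = sub.ndim
    counts = tuple((e - w) // stride + 1 for e, w in zip(sub.shape, win))
    total = np.zeros(counts, dtype=np.int64)
    for corner in product((0, 1), repeat=d):
        sign = (-1) ** (d - sum(corner))
        sl = tuple(
            slice(c * w, c * w + (n - 1) * stride + 1, stride)
            for c, w, n in zip(corner, win, counts)
        )
        total += sign * S[sl]
    return total.ravel()


def _sampled_window_sums(
    sub: np.ndarray,
    win: tuple[int, ...],
    stride: int,
    flat_positions: np.ndarray,
) -> np.ndarray:
    """Masses at a subset of stride-spaced window positions (flat indices)."""
    S = _prefix_sums(sub)
    d = sub.ndim
    counts = tuple((e - w) // stride + 1 for e, w in zip(sub.shape, win))
    starts = np.stack(np.unravel_index(flat_positions, counts), axis=1) * stride
    masses = np.zeros(len(flat_positions), dtype=np.int64)
    for corner in product((0, 1), repeat=d):
        sign = (-1) ** (d - sum(corner))
        idx = starts + np.asarray(corner) * np.asarray(win)
        masses += sign * S[tuple(idx.T)]
    return masses


def lacunarity_at_scale(
    occ: BinaryOccupancy,
    scale: int,
    stride: int = 1,
    subsample_rate: float = 1.0,
    seed: int | None = None,
    convention: LacunarityConvention = "one_plus_cv2",
    cap_window: bool = False,
    domain: Literal["bbox", "grid"] = "bbox",
) -> tuple[float, WindowMassStats]:
    """Gliding-box lacunarity Lambda(scale) and the underlying mass statistics.

    Windows are scale-sided hypercubes fully inside the gliding domain —
    the tight bounding box of occupied cells by default
    (``domain="grid"`` glides over the full grid as supplied, making the
    statistic sensitive to empty padding) — visited at the given stride.
    With
    ``subsample_rate < 1`` a uniform random sample without replacement of
    ``ceil(rate * n_positions)`` positions (minimum 2) is evaluated, seeded
    per scale; ``subsample_rate == 1`` enumerates every position and ignores
    the seed.  ``cap_window=True`` clips the window per axis to the axis
    extent (used by the 4D intensity lift, where the quantized-intensity
    axis may be shorter than the spatial axes).
    """
    scale = int(scale)
    if scale < 1:
        raise ValidationError(f"scale must be >= 1, got {scale}")
    if stride < 1:
        raise ValidationError(f"stride must be >= 1, got {stride}")
    if not 0.0 < subsample_rate <= 1.0:
        raise ValidationError(f"subsample_rate must be in (0, 1], got {subsample_rate}")
    if not occ.cells.any():
        raise EmptyMaskError("occupancy grid has no occupied cells")
    sub = occ.cropped() if domain == "bbox" else occ.cells
    if cap_window:
        win = tuple(min(scale, e) for e in sub.shape)
    else:
        if any(e < scale for e in sub.shape):
            raise ScaleTooLargeError(
                f"scale {scale} exceeds bounding box extent {sub.shape}"
            )
        win = (scale,) * sub.ndim
    counts = tuple((e - w) // stride + 1 for e, w in zip(sub.shape, win))
    n_positions = int(np.prod(counts))
    if n_positions < 2:
        raise ScaleTooLargeError(
            f"scale {scale} admits only {n_positions} gliding position(s) "
            f"in bounding box {sub.shape}; >= 2 required"
        )
    if subsample_rate >= 1.0:
        masses = _all_window_sums(sub, win, stride)
        used_seed = None
    else:
        k = min(max(2, math.ceil(subsample_rate * n_positions)), n_positions)
        rng = np.random.default_rng([0 if seed is None else seed, scale])
        flat = rng.choice(n_positions, size=k, replace=False)
        masses = _sampled_window_sums(sub, win, stride, flat)
        used_seed = 0 if seed is None else seed
    mu = float(masses.mean())
    if mu == 0.0:
        raise DegenerateWindowError(
            f"all {len(masses)} evaluated window masses are zero at scale {scale}"
        )
    var = float(masses.var())  # population variance
    cv2 = var / mu**2
    lam = 1.0 + cv2 if convention == "one_plus_cv2" else cv2
    stats = WindowMassStats(
        mean_mass=mu,
        variance=var,
        n_windows_evaluated=len(masses),
        subsample_rate=float(subsample_rate),
        seed=used_seed,
    )
    return lam, stats


def lacunarity_index(
    occ: BinaryOccupancy,
    scales: Sequence[int],
    stride: int = 1,
    subsample_rate: float = 1.0,
    seed: int | None = None,
    convention: LacunarityConvention = "one_plus_cv2",
    cap_window: bool = False,
    domain: Literal["bbox", "grid"] = "bbox",
    label: str | None = None,
) -> LIResult:
    """Lacunarity index: slope of ln Lambda(s) against ln(1/s) across scales.

    Scales where the lacunarity computation fails (window does not fit, or
    all masses zero) are dropped with a logged warning; the fit errors if
    fewer than 3 usable scales remain.  Under the literal ``cv2`` convention
    scales with Lambda = 0 (homogeneous mass) are likewise dropped, since
    their logarithm is undefined.
    """
    scales = sorted(int(s) for s in scales)
    if len(scales) < 3:
        raise InsufficientScalesError(f"need >= 3 scales, got {len(scales)}")
    kept_scales: list[int] = []
    lams: list[float] = []
    stats_list: list[WindowMassStats] = []
    for s in scales:
        try:
            lam, stats = lacunarity_at_scale(
                occ,
                s,
                stride=stride,
                subsample_rate=subsample_rate,
                seed=seed,
                convention=convention,
                cap_window=cap_window,
                domain=domain,
            )
        except (ScaleTooLargeError, DegenerateWindowError) as exc:
            logger.warning("dropping scale %d from lacunarity fit: %s", s, exc)
            continue
        if convention == "cv2" and lam == 0.0:
            logger.warning(
                "dropping scale %d: lacunarity 0 under cv2 convention (homogeneous masses)", s
            )
            continue
        kept_scales.append(s)
        lams.append(lam)
        stats_list.append(stats)
    if len(kept_scales) < 3:
        raise InsufficientScalesError(
            f"only {len(kept_scales)} usable scales of {scales}; >= 3 required"
        )
    series = ScaleSeries(tuple(kept_scales), tuple(lams), kind="lacunarity")
    fit = fit_loglog(series)
    return LIResult(
        li=fit.slope,
        fit=fit,
        series=series,
        per_scale_stats=tuple(stats_list),
        label=label,
    )
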