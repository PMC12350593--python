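"""Phantoms and synthetic cohorts with analytically known properties.

The study's patient data are not public, so this module supplies the test
substrate: deterministic 3D phantoms whose box-counting dimension is known
in closed form (Menger sponge ln20/ln3, solid cube 3, slab 2, line 1),
random tumor-like mask + intensity phantoms, and synthetic patient cohorts
drawn from a logistic model with configurable true weights.  All generators
are pure functions of their specification, seed included (numpy's PCG64
``default_rng``), so outputs are bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import ValidationError
from .fractal import BinaryOccupancy
from .intensity import IntensityVolume

PHANTOM_KINDS = (
    "menger_sponge",
    "solid_cube",
    "slab",
    "line",
    "ball",
    "checkerboard",
    "random_porous",
)

_MAX_SPONGE_ITER = 5


@dataclass(frozen=True)
class PhantomSpec:
    kind: str
    size: int = 0
    iteration: int = 0
    density: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValidationError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "random_porous":
            if self.density is None or not 0.0 < self.density < 1.0:
                raise ValidationError("random_porous requires density in (0, 1)")
            if self.seed is None:
                raise ValidationError("random_porous requires a seed")
        if self.kind != "menger_sponge" and self.size < 1:
            raise ValidationError("size must be >= 1")


# 3x3x3 keep-pattern of the Menger sponge: a subcube survives iff at most
# one of its coordinates is the center one.
_SPONGE_PATTERN = np.array(
    [
        [[(i == 1) + (j == 1) + (k == 1) <= 1 for k in range(3)] for j in range(3)]
        for i in range(3)
    ],
    dtype=bool,
)


def menger_sponge(k: int) -> BinaryOccupancy:
    """Menger sponge at iteration k: side 3^k, 20^k occupied cells.

    Box counts at scales 3^m equal 20^(k-m), so the box-counting dimension
    on base-3 scales is exactly ln 20 / ln 3.
    """
    if k < 0:
        raise ValidationError("iteration must be >= 0")
    if k > _MAX_SPONGE_ITER:
        raise ValidationError(
            f"iteration {k} exceeds the size guard ({_MAX_SPONGE_ITER}; "
            f"side would be {3**k} cells)"
        )
    cells = np.ones((1, 1, 1), dtype=bool)
    for _ in range(k):
        cells = np.kron(cells, _SPONGE_PATTERN)
    return BinaryOccupancy(cells)


def deterministic_phantom(spec: PhantomSpec) -> BinaryOccupancy:
    """Build a phantom of known geometry from its specification."""
    if spec.kind == "menger_sponge":
        return menger_sponge(spec.iteration)
    n = spec.size
    if spec.kind == "solid_cube":
        cells = np.ones((n, n, n), dtype=bool)
    elif spec.kind == "slab":
        cells = np.zeros((n, n, n), dtype=bool)
        cells[:, :, 0] = True
    elif spec.kind == "line":
        cells = np.zeros((n, n, n), dtype=bool)
        cells[:, 0, 0] = True
    elif spec.kind == "ball":
        c = (n - 1) / 2.0
        g = np.indices((n, n, n))
        r2 = sum((g[a] - c) ** 2 for a in range(3))
        cells = r2 <= (n / 2.0) ** 2
    elif spec.kind == "checkerboard":
        g = np.indices((n, n, n))
        cells = (g.sum(axis=0) % 2) == 0
    elif spec.kind == "random_porous":
        rng = np.random.default_rng(spec.seed)
        cells = rng.random((n, n, n)) < spec.density
        if not cells.any():  # vanishing probability at any realistic density
            cells[tuple(rng.integers(0, n, 3))] = True
    else:  # pragma: no cover - guarded by PhantomSpec
        raise ValidationError(spec.kind)
    return BinaryOccupancy(cells)


def tumor_phantom(
    seed: int,
    size: int = 32,
    smoothness: float | None = None,
    mask_quantile: float = 0.80,
    necrotic_core: bool = False,
    sequence_label: str = "other",
) -> IntensityVolume:
    """Random blob-like tumor phantom: connected mask + smooth intensity texture.

    The mask is the largest connected component of thresholded smoothed
    Gaussian noise biased toward the volume center; intensities are an
    independent smoothed noise texture.  With ``necrotic_core=True`` a
    central sphere of radius ~ 1/4 of the blob's equivalent radius is set to
    intensities below everything outside it, mimicking a necrotic or cystic
    component.
    """
    if size < 16:
        raise ValidationError("tumor phantom size must be >= 16")
    rng = np.random.default_rng(seed)
    if smoothness is None:
        smoothness = size / 8.0
    noise = ndimage.gaussian_filter(rng.standard_normal((size,) * 3), smoothness)
    g = np.indices((size,) * 3)
    c = (size - 1) / 2.0
    r = np.sqrt(sum((g[a] - c) ** 2 for a in range(3)))
    bias = np.exp(-((r / (size / 3.0)) ** 2))  # favor a central blob
    fld = noise / max(np.abs(noise).max(), 1e-12) + bias
    q = mask_quantile
    mask = fld > np.quantile(fld, q)
    for _ in range(5):
        if mask.any():
            break
        q -= 0.1
        mask = fld > np.quantile(fld, q)
    if not mask.any():
        raise ValidationError("tumor phantom mask empty after threshold relaxation")
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
        mask = labels == (int(np.argmax(sizes)) + 1)
    texture = ndimage.gaussian_filter(rng.standard_normal((size,) * 3), 2.0)
    values = (texture - texture.min()) / (texture.max() - texture.min()) * 900.0 + 100.0
    if necrotic_core:
        cz = np.array(ndimage.center_of_mass(mask))
        req = (3.0 * mask.sum() / (4.0 * np.pi)) ** (1.0 / 3.0)
        core = np.sqrt(sum((g[a] - cz[a]) ** 2 for a in range(3))) <= max(req / 4.0, 1.5)
        core &= mask
        if core.any():
            floor = values[mask & ~core].min() if (mask & ~core).any() else values.min()
            values[core] = floor * 0.1
    return IntensityVolume(values=values, mask=mask, sequence_label=sequence_label)


# ---------------------------------------------------------------------------
# Synthetic cohorts


@dataclass(frozen=True)
class CohortSpec:
    """Generative specification of a synthetic patient cohort.

    ``true_weights`` apply to [0,1]-scaled continuous features (scaled by
    the distribution's support for uniforms, by the empirical min-max for
    normals) and to raw 0/1 binary features; the binary label is drawn from
    logistic(intercept + sum(w * scaled feature)).
    """

    n: int
    feature_distributions: Mapping[str, tuple]
    true_weights: Mapping[str, float]
    intercept: float
    label: str
    seed: int
    positive_value: object = 1
    negative_value: object = 0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValidationError("cohort size must be >= 20")
        unknown = set(self.true_weights) - set(self.feature_distributions)
        if unknown:
            raise ValidationError(f"weights reference unknown features {sorted(unknown)}")


def synthetic_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw a cohort from the specification's logistic generative model.

    Columns are the feature names plus the label column; a degenerate draw
    (minority class below 5%) raises rather than returning an unusable
    cohort.
    """
    rng = np.random.default_rng(spec.seed)
    raw: dict[str, np.ndarray] = {}
    scaled: dict[str, np.ndarray] = {}
    for name, dist in spec.feature_distributions.items():
        kind = dist[0]
        if kind == "uniform":
            lo, hi = float(dist[1]), float(dist[2])
            x = rng.uniform(lo, hi, spec.n)
            raw[name] = x
            scaled[name] = (x - lo) / (hi - lo)
        elif kind == "normal":
            mu, sd = float(dist[1]), float(dist[2])
            x = rng.normal(mu, sd, spec.n)
            raw[name] = x
            span = x.max() - x.min()
            scaled[name] = (x - x.min()) / span if span > 0 else np.zeros(spec.n)
        elif kind == "bernoulli":
            p = float(dist[1])
            x = (rng.random(spec.n) < p).astype(int)
            raw[name] = x
            scaled[name] = x.astype(float)
        else:
            raise ValidationError(f"unknown distribution kind {kind!r} for {name!r}")
    eta = np.full(spec.n, spec.intercept, dtype=float)
    for name, w in spec.true_weights.items():
        eta += w * scaled[name]
    p = 1.0 / (1.0 + np.exp(-eta))
    positive = rng.random(spec.n) < p
    prevalence = positive.mean()
    if not 0.05 <= prevalence <= 0.95:
        raise ValidationError(
            f"degenerate cohort: positive prevalence {prevalence:.1%} "
            "(minority class below 5%)"
        )
    df = pd.DataFrame(raw)
    df[spec.label] = np.where(positive, spec.positive_value, spec.negative_value)
    return df


def paperlike_grade_spec(n: int = 500, seed: int = 0) -> CohortSpec:
    """Cohort preset emulating the published group differences for WHO grade.

    Effect directions only (magnitudes are invented): FD higher in grade 1,
    grade-2 patients younger, inhomogeneous enhancement and larger volume
    more common at higher grade.  Positive class is grade 2.
    """
    return CohortSpec(
        n=n,
        feature_distributions={
            "fd": ("uniform", 2.0, 3.0),
            "li_flair": ("uniform", 0.5, 3.5),
            "age": ("uniform", 25.0, 85.0),
            "tumor_volume": ("uniform", 5.0, 120.0),
            "homogeneous_enhancement": ("bernoulli", 0.5),
        },
        true_weights={
            "fd": -1.5,
            "age": -1.0,
            "tumor_volume": 1.0,
            "homogeneous_enhancement": -1.5,
        },
        intercept=1.3,
        label="grade_label",
        seed=seed,
        positive_value=2,
        negative_value=1,
    )


def paperlike_consistency_spec(n: int = 500, seed: int = 0) -> CohortSpec:
    """Cohort preset emulating the published group differences for consistency.

    LI higher in hard tumors, homogeneous enhancement more common in soft
    tumors.  Positive class is soft.
    """
    return CohortSpec(
        n=n,
        feature_distributions={
            "li_flair": ("uniform", 0.5, 3.5),
            "fd": ("uniform", 2.0, 3.0),
            "homogeneous_enhancement": ("bernoulli", 0.5),
        },
        true_weights={"li_flair": -1.5, "homogeneous_enhancement": 1.2},
        intercept=0.15,
        label="consistency_label",
        seed=seed,
        positive_value="soft",
        negative_value="hard",
    )
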