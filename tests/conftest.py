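"""Shared fixtures and independent brute-force oracles.

The oracles deliberately take a different route from the library: window
masses are materialized with ``sliding_window_view`` (every window
instantiated and summed) instead of prefix-sum inclusion-exclusion, and
log-log slopes come from ``np.polyfit`` instead of the closed-form OLS.
"""

from __future__ import annotations

import numpy as np
import pytest
from numpy.lib.stride_tricks import sliding_window_view

from voxfract import BinaryOccupancy


def crop_to_bbox(cells: np.ndarray) -> np.ndarray:
    idx = np.nonzero(cells)
    sl = tuple(slice(ax.min(), ax.max() + 1) for ax in idx)
    return cells[sl]


def brute_force_masses(
    cells: np.ndarray, window: tuple[int, ...], domain: str = "bbox"
) -> np.ndarray:
    """Every gliding-window mass, materialized window by window."""
    sub = crop_to_bbox(cells) if domain == "bbox" else cells
    views = sliding_window_view(sub.astype(np.int64), window)
    d = sub.ndim
    return views.reshape(-1, int(np.prod(window))).sum(axis=1)


def brute_force_lacunarity(
    cells: np.ndarray, scale: int, domain: str = "bbox"
) -> float:
    masses = brute_force_masses(cells, (scale,) * cells.ndim, domain=domain)
    mu = masses.mean()
    return 1.0 + masses.var() / mu**2


def brute_force_li(cells: np.ndarray, scales: list[int], domain: str = "bbox") -> float:
    lams = [brute_force_lacunarity(cells, s, domain=domain) for s in scales]
    coeffs = np.polyfit(-np.log(scales), np.log(lams), 1)
    return float(coeffs[0])


def brute_force_box_count(cells: np.ndarray, scale: int) -> int:
    """Partition box count by explicit iteration over partition boxes."""
    sub = crop_to_bbox(cells)
    count = 0
    ranges = [range(0, e, scale) for e in sub.shape]
    import itertools

    for corner in itertools.product(*ranges):
        sl = tuple(slice(c, c + scale) for c in corner)
        if sub[sl].any():
            count += 1
    return count


@pytest.fixture
def random_mask():
    def make(seed: int, shape=(12, 12, 12), density: float = 0.3) -> BinaryOccupancy:
        rng = np.random.default_rng(seed)
        cells = rng.random(shape) < density
        if not cells.any():
            cells[0, 0, 0] = True
        return BinaryOccupancy(cells)

    return make
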