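"""Shared fixtures and oracle helpers for the test suite.

All random inputs are generated programmatically with fixed seeds; the
brute-force oracles here are deliberately independent of the library's
fast paths (all-pairs distances instead of distance transforms,
coverage-count scans instead of quantiles).
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from contourdose import Mask, VoxelGrid, extract_surface


def make_mask(indices, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0),
              name="roi", origin=(0.0, 0.0, 0.0)) -> Mask:
    """Mask with foreground exactly at the given (z, y, x) indices."""
    grid = VoxelGrid(shape, spacing, origin)
    occ = np.zeros(shape, dtype=bool)
    for idx in indices:
        occ[tuple(idx)] = True
    return Mask(grid, occ, roi_name=name)


def block_mask(lo, hi, shape=(16, 16, 16), spacing=(1.0, 1.0, 1.0),
               name="block") -> Mask:
    """Solid axis-aligned block covering index ranges [lo, hi) per axis."""
    grid = VoxelGrid(shape, spacing)
    occ = np.zeros(shape, dtype=bool)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return Mask(grid, occ, roi_name=name)


def random_blob_mask(rng, shape=(10, 12, 14), spacing=(2.0, 1.0, 1.5),
                     name="blob") -> Mask:
    """Random connected-ish blob: thresholded smoothed noise, never empty."""
    from scipy import ndimage as ndi

    field = ndi.gaussian_filter(rng.standard_normal(shape), sigma=1.5)
    occ = field > np.quantile(field, 0.8)
    if not occ.any():  # pragma: no cover - quantile guarantees foreground
        occ[tuple(s // 2 for s in shape)] = True
    return Mask(VoxelGrid(shape, spacing), occ, roi_name=name)


def brute_force_surface_distances(a: Mask, b: Mask):
    """All-pairs oracle for the directed surface distance distributions."""
    pa = extract_surface(a).points
    pb = extract_surface(b).points
    d = cdist(pa, pb)
    return d.min(axis=1), d.min(axis=0)


def brute_force_hd_mda(a: Mask, b: Mask):
    d_ab, d_ba = brute_force_surface_distances(a, b)
    hd = max(d_ab.max(), d_ba.max())
    md = 0.5 * (d_ab.mean() + d_ba.mean())
    return float(hd), float(md)


def coverage_pct(doses: np.ndarray, d: float) -> float:
    """Scan oracle: percentage of voxels receiving at least d."""
    return 100.0 * np.count_nonzero(doses >= d) / doses.size


def dx_bracket(doses: np.ndarray, x_pct: float):
    """Count-based bracket [lo, hi] that must contain D_X.

    Covering at least x% of the volume takes the ``ceil(n*x/100)``
    hottest voxels; the step-function D_X is that voxel's dose, and an
    interpolating D_X must lie within one order statistic of it on either
    side.  Independent of any quantile routine: pure sort-and-count.
    """
    s = np.sort(np.asarray(doses, float))
    n = s.size
    k_star = int(np.ceil(n * x_pct / 100.0))  # hottest voxels needed
    i = n - k_star                            # ascending index of step D_X
    lo = s[max(i - 1, 0)]
    hi = s[min(i + 1, n - 1)]
    return float(lo), float(hi)


def scan_dx_exact(doses: np.ndarray, x_pct: float) -> float:
    """Largest observed dose with coverage >= x (step-function D_X)."""
    cand = np.unique(doses)
    ok = cand[np.array([coverage_pct(doses, d) >= x_pct for d in cand])]
    return float(ok.max())


@pytest.fixture
def rng():
    return np.random.default_rng(20230315)


@pytest.fixture(scope="session")
def small_anatomy_params():
    """Default-geometry anatomy used by several generator tests."""
    from contourdose import AnatomyParams

    return AnatomyParams(seed=7)
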