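"""Independent brute-force oracles used by the tests.

These deliberately avoid the library routines the implementation relies on
(scipy.ndimage morphology / EDT, cKDTree): dilation and erosion are built
from zero-fill array shifts, hole filling from an explicit flood fill, and
distances from all-pairs computations.
"""

import numpy as np


def shift(a: np.ndarray, axis: int, step: int, fill=False) -> np.ndarray:
    """Shift along one axis, filling vacated voxels with `fill` (no wrap)."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if step > 0:
        dst[axis], src[axis] = slice(step, None), slice(None, -step)
    elif step < 0:
        dst[axis], src[axis] = slice(None, step), slice(-step, None)
    else:
        return a.copy()
    out[tuple(dst)] = a[tuple(src)]
    return out


def dilate6(a: np.ndarray) -> np.ndarray:
    out = a.copy()
    for ax in range(3):
        for s in (-1, 1):
            out |= shift(a, ax, s, fill=False)
    return out


def erode6(a: np.ndarray) -> np.ndarray:
    out = a.copy()
    for ax in range(3):
        for s in (-1, 1):
            out &= shift(a, ax, s, fill=False)
    return out


def flood_fill_from_border(background: np.ndarray) -> np.ndarray:
    """Background voxels 6-connected to the volume border (iterative growth)."""
    seed = np.zeros_like(background)
    seed[0, :, :] = seed[-1, :, :] = True
    seed[:, 0, :] = seed[:, -1, :] = True
    seed[:, :, 0] = seed[:, :, -1] = True
    reach = background & seed
    while True:
        grown = dilate6(reach) & background
        if np.array_equal(grown, reach):
            return reach
        reach = grown


def oracle_close_and_fill(mask: np.ndarray, iterations: int = 10) -> np.ndarray:
    """Dilate^n / erode^n on a padded grid, crop, then fill enclosed holes."""
    k = iterations
    a = np.asarray(mask, dtype=bool)
    if k > 0:
        a = np.pad(a, k, constant_values=False)
        for _ in range(k):
            a = dilate6(a)
        for _ in range(k):
            a = erode6(a)
        a = a[k:-k, k:-k, k:-k]
    outside = flood_fill_from_border(~a)
    return a | (~a & ~outside)


def oracle_boundary(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 in-volume background face-neighbor."""
    fg = np.asarray(mask, dtype=bool)
    bg_neighbor = np.zeros_like(fg)
    for ax in range(3):
        for s in (-1, 1):
            bg_neighbor |= shift(~fg, ax, s, fill=False)
    return fg & bg_neighbor


def oracle_signed_distance(mask: np.ndarray, spacing=1.0) -> np.ndarray:
    """All-pairs signed distance (mm) to the nearest boundary voxel center."""
    fg = np.asarray(mask, dtype=bool)
    b = np.argwhere(oracle_boundary(fg)).astype(float) * spacing
    pts = np.indices(fg.shape).reshape(3, -1).T.astype(float) * spacing
    d2 = ((pts[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2.min(axis=1)).reshape(fg.shape)
    return np.where(fg, -d, d)


def oracle_hausdorff(a: np.ndarray, b: np.ndarray, spacing=1.0, percentile=100.0):
    """Symmetric boundary Hausdorff via the full all-pairs distance matrix."""
    pa = np.argwhere(oracle_boundary(a)).astype(float) * spacing
    pb = np.argwhere(oracle_boundary(b)).astype(float) * spacing
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    if percentile >= 100:
        return max(d_ab.max(), d_ba.max())
    return max(np.percentile(d_ab, percentile), np.percentile(d_ba, percentile))
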