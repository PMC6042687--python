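"""Independent brute-force reference implementations used only by the tests.

Every function here deliberately avoids the code paths (scipy.ndimage
labeling/EDT, scikit-image) the package uses, so agreement is a genuine
cross-check: plain loops, shifts and enumerations.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np

OFFSETS_26 = [
    (dz, dy, dx)
    for dz, dy, dx in product((-1, 0, 1), repeat=3)
    if (dz, dy, dx) != (0, 0, 0)
]


def _shift(mask: np.ndarray, off) -> np.ndarray:
    """Shift a boolean grid by an offset, zero-filling the borders."""
    out = np.zeros_like(mask)
    src = [slice(max(-o, 0), mask.shape[i] - max(o, 0)) for i, o in enumerate(off)]
    dst = [slice(max(o, 0), mask.shape[i] + min(o, 0)) for i, o in enumerate(off)]
    out[tuple(dst)] = mask[tuple(src)]
    return out


def hysteresis_bruteforce(img: np.ndarray, low: float, high: float) -> np.ndarray:
    """Flood fill from high-threshold seeds through >=low voxels (26-conn),
    implemented as iterative frontier growth with explicit shifts."""
    mask_low = img >= low
    grown = (img >= high).copy()
    while True:
        frontier = np.zeros_like(grown)
        for off in OFFSETS_26:
            frontier |= _shift(grown, off)
        new = frontier & mask_low & ~grown
        if not new.any():
            return grown
        grown |= new


def overlap_bruteforce(a: np.ndarray, ref: np.ndarray) -> float:
    inter = sum(
        1 for idx in np.ndindex(a.shape) if a[idx] and ref[idx]
    )
    return inter / int(ref.sum())


def intermixing_bruteforce(target: np.ndarray, others) -> float:
    hits = 0
    for idx in np.ndindex(target.shape):
        if target[idx] and any(o[idx] for o in others):
            hits += 1
    return hits / int(target.sum())


def contact_bruteforce(a: np.ndarray, b: np.ndarray) -> bool:
    """Exhaustive neighbor-offset check for overlap-or-26-adjacency."""
    if np.any(a & b):
        return True
    return any(np.any(_shift(a, off) & b) for off in OFFSETS_26)


def min_edge_distance_bruteforce(a: np.ndarray, b: np.ndarray, spacing) -> float:
    """Minimum over all voxel pairs of the anisotropic center distance."""
    if np.any(a & b):
        return 0.0
    sa = np.argwhere(a) * np.asarray(spacing)
    sb = np.argwhere(b) * np.asarray(spacing)
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def otsu_bruteforce(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximisation over midpoints of the
    sorted unique values."""
    vals = np.sort(np.unique(values.astype(float)))
    best_t, best_var = None, -1.0
    for lo, hi in zip(vals[:-1], vals[1:]):
        t = (lo + hi) / 2.0
        g0 = values[values <= t]
        g1 = values[values > t]
        w0, w1 = len(g0) / len(values), len(g1) / len(values)
        var = w0 * w1 * (g0.mean() - g1.mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def fisher_bruteforce(table) -> float:
    """Two-sided Fisher exact p by hypergeometric enumeration over all tables
    with the observed margins."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = pmf(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs * (1 + 1e-9))


def radius_of_gyration(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def random_blob_mask(rng: np.random.Generator, shape, n_blobs=3, max_r=4) -> np.ndarray:
    """A small random union-of-boxes mask for oracle-equivalence tests."""
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        c = [rng.integers(0, s) for s in shape]
        r = [int(rng.integers(1, max_r + 1)) for _ in shape]
        sl = tuple(slice(max(c[i] - r[i], 0), min(c[i] + r[i] + 1, shape[i])) for i in range(3))
        mask[sl] = True
    return mask
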