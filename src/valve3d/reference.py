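"""Brute-force reference implementations used to validate the fast algorithms.

Each function here recomputes a quantity by direct enumeration or flood fill,
with no shortcuts shared with the production code path. They are slow on
purpose and intended for small inputs inside tests and validation reports.
"""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np

__all__ = [
    "exhaustive_multiotsu",
    "flood_fill_label",
    "brute_force_thickness",
    "mann_whitney_enumerate",
]

_COMBO_CACHE: dict = {}


def _all_cut_tuples(n_thresholds: int) -> np.ndarray:
    """All strictly increasing threshold tuples over gray values 1..255 (lex order)."""
    key = n_thresholds
    if key not in _COMBO_CACHE:
        combos = np.array(
            list(itertools.combinations(range(1, 256), n_thresholds)), dtype=np.int64
        )
        _COMBO_CACHE[key] = combos
    return _COMBO_CACHE[key]


def exhaustive_multiotsu(gray_histogram: np.ndarray, n_thresholds: int = 3) -> tuple:
    """Flat enumeration of every increasing threshold tuple; first (lex-smallest) argmax.

    Maximizes the between-class variance, i.e. sum over classes of S^2/W
    (S = gray-weighted count, W = count; empty classes contribute 0).
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    if hist.size < 256:
        hist = np.pad(hist, (0, 256 - hist.size))
    levels = np.arange(256, dtype=np.float64)
    cw = np.concatenate(([0.0], np.cumsum(hist)))
    cs = np.concatenate(([0.0], np.cumsum(hist * levels)))

    cuts = _all_cut_tuples(n_thresholds)
    bounds = np.concatenate(
        [np.zeros((cuts.shape[0], 1), dtype=np.int64), cuts,
         np.full((cuts.shape[0], 1), 256, dtype=np.int64)], axis=1)
    total = np.zeros(cuts.shape[0])
    for k in range(bounds.shape[1] - 1):
        w = cw[bounds[:, k + 1]] - cw[bounds[:, k]]
        s = cs[bounds[:, k + 1]] - cs[bounds[:, k]]
        with np.errstate(divide="ignore", invalid="ignore"):
            total += np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
    best = int(np.argmax(total))  # first occurrence = lexicographically smallest
    return tuple(int(c) for c in cuts[best])


def _offsets(connectivity: int):
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return offs


def flood_fill_label(mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Breadth-first flood-fill labeling; ids in raster order of first voxel."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    offs = _offsets(connectivity)
    nz, ny, nx = mask.shape
    current = 0
    for z, y, x in np.argwhere(mask):
        if labels[z, y, x]:
            continue
        current += 1
        queue = deque([(int(z), int(y), int(x))])
        labels[z, y, x] = current
        while queue:
            cz, cy, cx = queue.popleft()
            for dz, dy, dx in offs:
                tz, ty, tx = cz + dz, cy + dy, cx + dx
                if 0 <= tz < nz and 0 <= ty < ny and 0 <= tx < nx \
                        and mask[tz, ty, tx] and not labels[tz, ty, tx]:
                    labels[tz, ty, tx] = current
                    queue.append((tz, ty, tx))
    return labels


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Largest-inscribed-sphere thickness by painting every voxel's maximal sphere.

    Same digital convention as :func:`valve3d.thickness.local_thickness`
    (sphere of squared radius R2 covers |p-q|^2 <= R2-1; diameter
    2*(sqrt(R2)-0.5)), but no pruning, no ordering: the max over all spheres
    is taken directly. Result is in voxel units.
    """
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.float64)
    if not mask.any():
        return out
    from scipy import ndimage

    padded = np.pad(mask, 1, constant_values=False)
    r2 = np.rint(ndimage.distance_transform_edt(padded) ** 2).astype(np.int64)
    r2 = r2[tuple(slice(1, -1) for _ in range(mask.ndim))]

    shape = mask.shape
    for z, y, x in np.argwhere(mask):
        rr2 = int(r2[z, y, x])
        rad = math.isqrt(max(rr2 - 1, 0))
        value = 2.0 * (math.sqrt(rr2) - 0.5)
        z0, z1 = max(0, z - rad), min(shape[0], z + rad + 1)
        y0, y1 = max(0, y - rad), min(shape[1], y + rad + 1)
        x0, x1 = max(0, x - rad), min(shape[2], x + rad + 1)
        zz, yy, xx = np.ogrid[z0 - z:z1 - z, y0 - y:y1 - y, x0 - x:x1 - x]
        inside = (zz * zz + yy * yy + xx * xx) <= (rr2 - 1)
        sub = out[z0:z1, y0:y1, x0:x1]
        np.maximum(sub, np.where(inside, value, 0.0), out=sub)
    return out


def mann_whitney_enumerate(group_a, group_b) -> tuple:
    """Exact two-sided Mann-Whitney p by full enumeration of group assignments.

    Midranks handle ties. Returns (U of group_a, two-sided p) with the
    two-sided p defined as P(|U - n_a n_b / 2| >= |u_obs - n_a n_b / 2|).
    """
    from scipy.stats import rankdata

    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    na, nb = len(a), len(b)
    mu = na * nb / 2.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2.0
    d_obs = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(na + nb), na):
        u = ranks[list(idx)].sum() - na * (na + 1) / 2.0
        total += 1
        if abs(u - mu) >= d_obs - 1e-9:
            hits += 1
    return float(u_obs), hits / total
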