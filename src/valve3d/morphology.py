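"""Shared morphological primitives (structuring elements and k-voxel dilation)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["square_xy", "cube", "dilation_structure", "dilate_by_voxels",
           "close_slicewise", "open_slicewise"]


def square_xy(size: int) -> np.ndarray:
    """A size x size square kernel acting within XY slices of a (z, y, x) volume."""
    return np.ones((1, size, size), dtype=bool)


def cube(size: int) -> np.ndarray:
    return np.ones((size, size, size), dtype=bool)


def dilation_structure(mode: str) -> np.ndarray:
    """One-step dilation structure: 3x3x3 cube ('cube') or 6-connected cross ('ball')."""
    if mode == "cube":
        return ndimage.generate_binary_structure(3, 3)
    if mode == "ball":
        return ndimage.generate_binary_structure(3, 1)
    raise ValueError("mode must be 'cube' or 'ball'")


def dilate_by_voxels(mask: np.ndarray, k: int, mode: str = "cube") -> np.ndarray:
    """Dilate ``mask`` by ``k`` voxels: k iterations of the one-step structure."""
    if k == 0:
        return mask.copy()
    return ndimage.binary_dilation(mask, structure=dilation_structure(mode), iterations=k)


def close_slicewise(mask: np.ndarray, size: int, three_d: bool = False) -> np.ndarray:
    """Morphological closing with a square kernel per XY slice (or a cube if 3D).

    Computed on the infinite domain (outside the array is background): the
    array is padded by the kernel radius before closing so that structures
    touching the volume border are not eroded by the border handling.
    """
    structure = cube(size) if three_d else square_xy(size)
    pad = tuple((s // 2, s // 2) for s in structure.shape)
    padded = np.pad(mask, pad, constant_values=False)
    closed = ndimage.binary_closing(padded, structure=structure)
    slices = tuple(slice(p0, dim - p1) for (p0, p1), dim in zip(pad, padded.shape))
    return closed[slices]


def open_slicewise(mask: np.ndarray, size: int) -> np.ndarray:
    """Morphological opening with a square kernel per XY slice.

    Opening is invariant to translations of the structuring element, so the
    anchoring of even-sized kernels does not affect the result.
    """
    return ndimage.binary_opening(mask, structure=square_xy(size))
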