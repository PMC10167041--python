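"""Slice-stack IO, 16->8 bit conversion and two-material gray normalization.

Reconstructed microCT volumes arrive as a directory of 2D grayscale slices
(XY planes, stacked along Z in lexicographic filename order). Datasets from
different scans live on different gray scales; to make one set of density
thresholds applicable to all of them, every dataset is mapped onto the scale
of a chosen reference dataset using two materials present in every scan
(a borosilicate bead and the sample holder) as gray anchors.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import tifffile
import imageio.v3 as iio

__all__ = [
    "ImageVolume",
    "ReferenceAnchors",
    "read_stack",
    "write_stack",
    "convert_16_to_8",
    "normalize_to_reference",
    "measure_anchor",
    "round_half_away",
]

_TIFF_EXT = {".tif", ".tiff"}
_OTHER_EXT = {".bmp", ".png"}


def round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3).

    Used everywhere gray values are re-quantized, to keep the endpoint
    examples (e.g. 127.5 -> 128) deterministic across platforms.
    """
    x = np.asarray(x, dtype=np.float64)
    out = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return out if out.ndim else float(out)


@dataclass
class ImageVolume:
    """Isotropic 3D grayscale volume.

    ``data`` is indexed ``[z, y, x]``: each ``data[k]`` is one XY slice.
    ``voxel_size_um`` is the (single, isotropic) physical edge length of a
    voxel in micrometres.
    """

    data: np.ndarray
    voxel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume must be a non-empty 3D array")
        if np.ndim(self.voxel_size_um) != 0:
            raise ValueError(
                "voxel_size_um must be a single scalar: anisotropic voxels "
                "are not supported"
            )
        self.voxel_size_um = float(self.voxel_size_um)
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be > 0")
        if self.data.dtype not in (np.uint8, np.uint16):
            raise ValueError(f"unsupported dtype {self.data.dtype}; use uint8 or uint16")

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.voxel_size_um)


@dataclass
class ReferenceAnchors:
    """Mean gray values of the two reference materials in two datasets.

    ``target_*`` are measured on the dataset being normalized, ``ref_*`` on
    the reference dataset whose gray scale defines the thresholds.
    """

    target_holder: float
    target_bead: float
    ref_holder: float
    ref_bead: float

    def __post_init__(self) -> None:
        for v in (self.target_holder, self.target_bead, self.ref_holder, self.ref_bead):
            if not (0.0 <= v <= 255.0):
                raise ValueError("anchor means must lie in [0, 255]")
        if self.target_bead == self.target_holder:
            raise ValueError("degenerate anchors: target bead and holder means are equal")
        if self.ref_bead == self.ref_holder:
            raise ValueError("degenerate anchors: reference bead and holder means are equal")


def _read_slice(path: str) -> np.ndarray:
    ext = os.path.splitext(path)[1].lower()
    if ext in _TIFF_EXT:
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    img = np.asarray(img)
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        # grayscale stored as identical channels
        if not (img[..., :3] == img[..., :1]).all():
            raise ValueError(f"{path}: color image; expected single-channel grayscale")
        img = img[..., 0]
    if img.ndim != 2:
        raise ValueError(f"{path}: expected a 2D slice, got shape {img.shape}")
    return img


def read_stack(directory_path: str, voxel_size_um: float) -> ImageVolume:
    """Read a directory of grayscale slices into a volume.

    Slice order along Z is the lexicographic sort of the file names.
    All slices must share width, height and bit depth.
    """
    names = sorted(
        n for n in os.listdir(directory_path)
        if os.path.splitext(n)[1].lower() in (_TIFF_EXT | _OTHER_EXT)
    )
    if not names:
        raise ValueError(f"no slice images found in {directory_path!r}")
    slices = [_read_slice(os.path.join(directory_path, n)) for n in names]
    shape0, dtype0 = slices[0].shape, slices[0].dtype
    for n, s in zip(names, slices):
        if s.shape != shape0:
            raise ValueError(f"mixed slice dimensions: {n} is {s.shape}, expected {shape0}")
        if s.dtype != dtype0:
            raise ValueError(f"mixed bit depths: {n} is {s.dtype}, expected {dtype0}")
    return ImageVolume(np.stack(slices, axis=0), voxel_size_um)


def write_stack(volume: ImageVolume | np.ndarray, directory_path: str,
                prefix: str = "slice", fmt: str = "tiff") -> list:
    """Write a volume as one file per Z slice with zero-padded numeric suffixes.

    ``fmt`` is ``"tiff"`` (any supported dtype) or ``"bmp"`` (8-bit only).
    Returns the list of written paths.
    """
    data = volume.data if isinstance(volume, ImageVolume) else np.asarray(volume)
    os.makedirs(directory_path, exist_ok=True)
    if fmt not in ("tiff", "bmp"):
        raise ValueError("fmt must be 'tiff' or 'bmp'")
    if fmt == "bmp" and data.dtype != np.uint8:
        raise ValueError("BMP output requires an 8-bit volume")
    width = max(4, len(str(data.shape[0] - 1)))
    ext = ".tiff" if fmt == "tiff" else ".bmp"
    paths = []
    for k in range(data.shape[0]):
        path = os.path.join(directory_path, f"{prefix}_{k:0{width}d}{ext}")
        if fmt == "tiff":
            tifffile.imwrite(path, data[k])
        else:
            iio.imwrite(path, data[k])
        paths.append(path)
    return paths


def convert_16_to_8(volume16: ImageVolume,
                    percentile_clip: tuple | None = None) -> ImageVolume:
    """Convert a 16-bit volume to 8-bit, stretching to the dataset's dynamic range.

    The linear map sends the dataset minimum to 0 and the maximum to 255,
    rounding half away from zero. With ``percentile_clip=(lo, hi)`` the
    range endpoints are the given percentiles instead of the strict extrema
    (values beyond them are clamped); off by default.
    """
    data = volume16.data.astype(np.float64)
    if percentile_clip is not None:
        lo, hi = np.percentile(data, percentile_clip)
    else:
        lo, hi = data.min(), data.max()
    if hi <= lo:
        raise ValueError("degenerate gray range: volume has fewer than 2 distinct values")
    scaled = round_half_away((data - lo) * (255.0 / (hi - lo)))
    out = np.clip(scaled, 0, 255).astype(np.uint8)
    return ImageVolume(out, volume16.voxel_size_um)


def normalize_to_reference(volume8: ImageVolume, anchors: ReferenceAnchors) -> ImageVolume:
    """Map a dataset's gray scale onto the reference scale via the two anchors.

    Applies the unique affine gray map sending the target's
    (holder mean, bead mean) to the reference's, rounds half away from zero
    and clamps to [0, 255]. Re-measuring the anchor regions on the output
    reproduces the reference anchors to within +/-1 gray level.
    """
    if volume8.data.dtype != np.uint8:
        raise ValueError("normalize_to_reference expects an 8-bit volume")
    scale = (anchors.ref_bead - anchors.ref_holder) / (anchors.target_bead - anchors.target_holder)
    mapped = (volume8.data.astype(np.float64) - anchors.target_holder) * scale + anchors.ref_holder
    out = np.clip(round_half_away(mapped), 0, 255).astype(np.uint8)
    return ImageVolume(out, volume8.voxel_size_um)


def measure_anchor(volume8: ImageVolume, region_mask: np.ndarray) -> float:
    """Arithmetic mean gray value under a (non-empty) region mask."""
    mask = np.asarray(region_mask, dtype=bool)
    if mask.shape != volume8.data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {volume8.data.shape}")
    if not mask.any():
        raise ValueError("anchor region mask is empty")
    return float(volume8.data[mask].mean())
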