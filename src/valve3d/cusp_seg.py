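"""Whole-cusp segmentation (soft tissue + calcification) and mask volumetry."""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .io_norm import ImageVolume
from .morphology import close_slicewise

__all__ = ["segment_cusp", "mask_volume_mm3", "voxel_volume_mm3"]


def segment_cusp(volume8: ImageVolume, config: PipelineConfig | None = None,
                 roi_mask: np.ndarray | None = None) -> np.ndarray:
    """Segment the entire cusp from background.

    Thresholds at ``[cusp_threshold, 255]`` (inclusive), restricted to the
    region of interest (which removes the sample holder and bead), then
    closes small holes with a ``closing_kernel`` square applied per XY slice
    (or a cube if ``config.closing_3d``).

    The ROI mask is supplied externally (drawn manually on real scans; the
    phantom generator provides it programmatically).
    """
    config = config or PipelineConfig()
    if volume8.data.dtype != np.uint8:
        raise ValueError("segment_cusp expects an 8-bit volume")
    mask = volume8.data >= config.cusp_threshold
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != mask.shape:
            raise ValueError(f"roi_mask shape {roi_mask.shape} != volume shape {mask.shape}")
        mask &= roi_mask
    return close_slicewise(mask, config.closing_kernel, three_d=config.closing_3d)


def voxel_volume_mm3(voxel_size_um: float) -> float:
    return (voxel_size_um / 1000.0) ** 3


def mask_volume_mm3(mask: np.ndarray, voxel_size_um: float) -> float:
    """Physical volume of a binary mask: voxel count x (voxel edge in mm)^3."""
    return int(np.count_nonzero(mask)) * voxel_volume_mm3(voxel_size_um)
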