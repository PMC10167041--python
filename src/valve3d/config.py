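"""Pipeline configuration: every numeric parameter of the quantification protocol.

All gray-value thresholds refer to the normalized 8-bit scale (the scale on
which the pooled multilevel-Otsu thresholds 75/139/197 were derived). Keeping
them in one record makes every run auditable: the full config is snapshotted
into each :class:`~valve3d.report.CuspReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple


@dataclass
class PipelineConfig:
    """Numeric parameters of the cusp/calcification quantification protocol.

    Parameters
    ----------
    cusp_threshold:
        Lower gray bound of the whole-cusp segmentation (inclusive); the
        range is ``[cusp_threshold, 255]``.
    calc_threshold_low, calc_threshold_mid, calc_threshold_high:
        Lower gray bounds of the low/moderate/high density classes
        (inclusive).  The overall calcification range is
        ``[calc_threshold_low, 255]``.
    closing_kernel:
        Edge length of the square closing kernel used to fill small holes in
        the cusp mask (applied per XY slice unless ``closing_3d``).
    opening_kernel:
        Edge length of the square opening kernel applied to the MD and LD
        selections during partial-volume correction.
    hd_dilation_voxels:
        Dilation applied to the high-density selection before removing its
        halo from the cusp domain.
    compensation_dilation_voxels:
        Final per-class dilation compensating the volume lost to the halo
        removal and opening.
    min_particle_voxels:
        Particles of this many voxels or fewer are discarded.
    size_bounds_mm3:
        (micro/meso, meso/macro) particle-volume boundaries in mm^3.
        Micro is closed above, macro closed below.
    thin_threshold_mm:
        Thickness below which cusp tissue counts as "normal thickness".
    connectivity:
        Particle adjacency: 6 (faces), 18 (faces+edges) or 26 (full).
    closing_3d:
        If True, the cusp closing uses a cubic kernel instead of the
        slice-wise square.
    dilation_mode:
        ``"cube"`` (Chebyshev ball, 3x3x3 per step) or ``"ball"``
        (Euclidean unit ball, i.e. the 6-connected cross per step).
    percentile_clip:
        Optional (low, high) percentiles for robust 16->8 bit range
        normalization; ``None`` uses the strict dataset min/max.
    """

    cusp_threshold: int = 25
    calc_threshold_low: int = 75
    calc_threshold_mid: int = 139
    calc_threshold_high: int = 197
    closing_kernel: int = 5
    opening_kernel: int = 2
    hd_dilation_voxels: int = 2
    compensation_dilation_voxels: int = 1
    min_particle_voxels: int = 10
    size_bounds_mm3: Tuple[float, float] = (1e-3, 1.0)
    thin_threshold_mm: float = 0.7
    connectivity: int = 26
    closing_3d: bool = False
    dilation_mode: str = "cube"
    percentile_clip: Tuple[float, float] | None = None
    histogram_bin_width_mm: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.cusp_threshold < self.calc_threshold_low
                < self.calc_threshold_mid < self.calc_threshold_high <= 255):
            raise ValueError(
                "thresholds must satisfy 0 < cusp < low < mid < high <= 255, got "
                f"{self.cusp_threshold}/{self.calc_threshold_low}/"
                f"{self.calc_threshold_mid}/{self.calc_threshold_high}"
            )
        if self.size_bounds_mm3[0] >= self.size_bounds_mm3[1]:
            raise ValueError("size_bounds_mm3 must be strictly increasing")
        # kernels: >= 1; size-2 kernels are legitimate (the opening uses one),
        # so oddness is deliberately not required.
        for name in ("closing_kernel", "opening_kernel"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.dilation_mode not in ("cube", "ball"):
            raise ValueError("dilation_mode must be 'cube' or 'ball'")
        if self.min_particle_voxels < 0:
            raise ValueError("min_particle_voxels must be >= 0")
        if self.thin_threshold_mm <= 0:
            raise ValueError("thin_threshold_mm must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["size_bounds_mm3"] = list(self.size_bounds_mm3)
        if self.percentile_clip is not None:
            d["percentile_clip"] = list(self.percentile_clip)
        return d
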