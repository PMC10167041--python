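"""Connected-component particle labeling, small-particle filtering and morphometry.

A calcified particle is a maximal set of mutually connected calcification
voxels (all densities pooled). Particles are classified by physical volume:
microscale (<= 1e-3 mm^3), mesoscale (between), macroscale (>= 1 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import PipelineConfig
from .cusp_seg import voxel_volume_mm3

__all__ = ["label_particles", "filter_small", "particle_metrics", "ParticleTable"]

SIZE_CLASSES = ("micro", "meso", "macro")


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, rank[connectivity])


def _relabel_raster_order(labels: np.ndarray, n: int) -> np.ndarray:
    """Remap label ids to the raster-scan order of each component's first voxel."""
    if n == 0:
        return labels
    flat = labels.ravel()
    nz = np.flatnonzero(flat)
    # first occurrence of each label in raster order
    first = np.full(n + 1, flat.size, dtype=np.int64)
    # reversed so that earlier occurrences overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")  # old label-1 sorted by first voxel
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[order + 1] = np.arange(1, n + 1)
    return remap[labels]


def label_particles(calc_mask: np.ndarray, connectivity: int = 26) -> np.ndarray:
    """Label connected components of a binary mask.

    Adjacency is 6 (faces), 18 (faces+edges) or 26 (faces+edges+corners;
    default). Ids are 1..K, assigned in raster-scan order of each
    component's first voxel; 0 is background.
    """
    calc_mask = np.asarray(calc_mask, dtype=bool)
    labels, n = ndimage.label(calc_mask, structure=_structure(connectivity))
    return _relabel_raster_order(labels, n)


def filter_small(labels: np.ndarray, min_particle_voxels: int = 10) -> np.ndarray:
    """Drop particles of ``min_particle_voxels`` voxels or fewer; recompact ids to 1..K'.

    The boundary is inclusive: with the default of 10, a 10-voxel particle is
    removed and an 11-voxel particle kept.
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return labels.copy()
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    keep = counts > min_particle_voxels
    keep[0] = False
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, int(keep.sum()) + 1)
    return remap[labels]


@dataclass
class ParticleTable:
    """Per-particle morphometry plus per-sample summary statistics."""

    table: pd.DataFrame          # columns: id, voxel_count, volume_mm3, size_class
    n_particles: int
    n_per_class: dict            # micro/meso/macro -> count
    largest_volume_mm3: float
    largest_fraction: float      # largest particle / total particle volume
    particles_per_mm3: float     # count / entire-cusp volume
    size_bounds_voxels: tuple = field(default=(np.nan, np.nan))

    def summary(self) -> dict:
        return {
            "n_particles": self.n_particles,
            "n_per_class": dict(self.n_per_class),
            "largest_volume_mm3": self.largest_volume_mm3,
            "largest_fraction": self.largest_fraction,
            "particles_per_mm3": self.particles_per_mm3,
            "size_bounds_voxels": list(self.size_bounds_voxels),
        }


def classify_volume_mm3(volume_mm3, bounds_mm3=(1e-3, 1.0)):
    """Size class of a particle volume: micro (<= lower bound), macro (>= upper), meso otherwise.

    Boundary comparisons carry a 1e-9 relative tolerance so that a volume
    computed as voxel_count x voxel_volume lands in the intended class when
    it equals a boundary up to floating-point rounding.
    """
    v = np.asarray(volume_mm3, dtype=np.float64)
    lo, hi = bounds_mm3
    cls = np.where(v <= lo * (1 + 1e-9), "micro",
                   np.where(v >= hi * (1 - 1e-9), "macro", "meso"))
    return cls if cls.ndim else str(cls)


def particle_metrics(labels: np.ndarray, cusp_volume_mm3: float,
                     voxel_size_um: float,
                     config: PipelineConfig | None = None) -> ParticleTable:
    """Morphometry of (already filtered) labeled particles.

    ``particles_per_mm3`` normalizes the particle count by the entire-cusp
    volume — the only per-sample volume defined — and
    ``largest_fraction`` is the largest particle's share of the total
    particle volume. The class boundaries expressed in voxels for the given
    voxel size are recorded for auditability.
    """
    config = config or PipelineConfig()
    if cusp_volume_mm3 <= 0:
        raise ZeroDivisionError("cusp_volume_mm3 must be > 0")
    labels = np.asarray(labels)
    n = int(labels.max())
    vox_mm3 = voxel_volume_mm3(voxel_size_um)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:] if n else np.zeros(0, int)
    volumes = counts * vox_mm3
    classes = classify_volume_mm3(volumes, config.size_bounds_mm3) if n else np.array([], dtype=str)
    table = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "voxel_count": counts.astype(int),
        "volume_mm3": volumes,
        "size_class": classes,
    })
    n_per_class = {c: int((table["size_class"] == c).sum()) for c in SIZE_CLASSES}
    total = float(volumes.sum())
    largest = float(volumes.max()) if n else 0.0
    return ParticleTable(
        table=table,
        n_particles=n,
        n_per_class=n_per_class,
        largest_volume_mm3=largest,
        largest_fraction=(largest / total) if total > 0 else float("nan"),
        particles_per_mm3=n / cusp_volume_mm3,
        size_bounds_voxels=(config.size_bounds_mm3[0] / vox_mm3,
                            config.size_bounds_mm3[1] / vox_mm3),
    )
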