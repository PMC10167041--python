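"""Calcification segmentation, density decomposition and partial-volume correction.

Calcification in the normalized 8-bit volumes occupies gray values 75-255,
further split into low (75-138), moderate (139-196) and high (197-255)
density strata; the three class boundaries are the pooled multilevel-Otsu
thresholds. Because the point-spread function blurs every density step,
edge voxels of a dense particle take intermediate gray values and would be
mis-assigned to a lower density class (the partial volume effect, PVE). The
correction protocol segments the high-density cores first, removes their
dilated halo from the domain before segmenting the weaker classes, opens the
weaker selections, and finally dilates every class by one voxel to give back
the volume the halo removal and opening took away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .cusp_seg import mask_volume_mm3
from .io_norm import ImageVolume
from .morphology import dilate_by_voxels, open_slicewise

__all__ = [
    "multilevel_otsu",
    "pooled_thresholds",
    "segment_calcification",
    "calc_volume_fraction",
    "pve_decompose",
    "DensityMasks",
]


def _interval_table(hist: np.ndarray) -> np.ndarray:
    """between-class variance contribution of every bin interval [a, b).

    Entry ``(a, b)`` is ``S(a,b)^2 / W(a,b)`` where ``W`` is the interval's
    count and ``S`` its gray-weighted count; empty intervals contribute 0.
    Maximizing the sum of these contributions over a partition of [0, 256)
    is equivalent to maximizing the between-class variance.
    """
    levels = np.arange(hist.size, dtype=np.float64)
    cum_w = np.concatenate(([0.0], np.cumsum(hist)))
    cum_s = np.concatenate(([0.0], np.cumsum(hist * levels)))
    w = cum_w[None, :] - cum_w[:, None]   # (a, b) -> W over [a, b)
    s = cum_s[None, :] - cum_s[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(w > 0, s * s / np.where(w > 0, w, 1.0), 0.0)
    return term


def multilevel_otsu(gray_histogram: np.ndarray, n_thresholds: int = 3) -> tuple:
    """Thresholds maximizing the between-class variance of the histogram.

    Parameters
    ----------
    gray_histogram:
        Occurrence counts per gray value, length 256 (shorter histograms are
        zero-padded). Typically computed over cusp voxels only, so that
        background air does not dominate the class variance.
    n_thresholds:
        Number of thresholds; the histogram is split into
        ``n_thresholds + 1`` classes ``[0,t1), [t1,t2), ..., [tn, 256)``.
        Each returned threshold is the lowest gray value of its upper class
        (so a threshold of 75 means "calcified" is 75 and up).

    Ties are broken by the lexicographically smallest threshold tuple. The
    search is an exact dynamic program over the interval table; it returns
    the same optimum as brute-force enumeration of all increasing tuples
    (see :func:`valve3d.reference.exhaustive_multiotsu`).
    """
    hist = np.asarray(gray_histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size > 256:
        raise ValueError("histogram must be 1D with at most 256 bins")
    if (hist < 0).any():
        raise ValueError("histogram counts must be non-negative")
    if hist.size < 256:
        hist = np.pad(hist, (0, 256 - hist.size))
    if n_thresholds < 1:
        raise ValueError("n_thresholds must be >= 1")
    occupied = int(np.count_nonzero(hist))
    if occupied < n_thresholds + 1:
        raise ValueError(
            f"degenerate histogram: {occupied} occupied bins cannot form "
            f"{n_thresholds + 1} classes"
        )

    term = _interval_table(hist)
    n_pos = 257  # cut positions 0..256; thresholds are interior cuts 1..255

    # g[a] = best total contribution of splitting [a, 256) into k classes.
    # Level k=1: one class, no further cuts.
    g = term[:, 256].copy()
    best_next = [None] * (n_thresholds)  # best_next[k-1][a]: argmax cut for k+1 classes
    pos = np.arange(n_pos)
    for k in range(1, n_thresholds + 1):
        # cuts c must leave room: a < c <= 255 - (k - 1)
        cand = term[:, :n_pos] + g[None, :]
        invalid = (pos[None, :] <= pos[:, None]) | (pos > 255 - (k - 1))[None, :]
        cand = np.where(invalid, -np.inf, cand)
        choice = np.argmax(cand, axis=1)          # first occurrence = smallest cut
        g_new = cand[pos, choice]
        best_next[n_thresholds - k] = choice
        g = g_new

    thresholds = []
    a = 0
    for k in range(n_thresholds):
        a = int(best_next[k][a])
        thresholds.append(a)
    return tuple(thresholds)


def pooled_thresholds(per_sample_thresholds) -> tuple:
    """Pool per-sample threshold triples: component-wise mean (+/- SD).

    Returns ``(means, sds)`` where ``means`` is the component-wise arithmetic
    mean rounded half away from zero and ``sds`` the component-wise sample
    standard deviation (ddof=1; 0.0 for a single sample). Raises if the
    rounded means are not strictly increasing.
    """
    arr = np.asarray(list(per_sample_thresholds), dtype=np.float64)
    if arr.size == 0:
        raise ValueError("no threshold tuples supplied")
    if arr.ndim == 1:
        arr = arr[None, :]
    from .io_norm import round_half_away

    means = round_half_away(arr.mean(axis=0)).astype(int)
    sds = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
    if not np.all(np.diff(means) > 0):
        raise ValueError(f"pooled thresholds are not strictly increasing: {tuple(means)}")
    return tuple(int(m) for m in means), tuple(float(s) for s in sds)


def segment_calcification(volume8: ImageVolume, cusp_mask: np.ndarray,
                          config: PipelineConfig | None = None) -> np.ndarray:
    """All calcification, densities pooled: gray in [calc_threshold_low, 255] within the cusp."""
    config = config or PipelineConfig()
    cusp_mask = np.asarray(cusp_mask, dtype=bool)
    if cusp_mask.shape != volume8.data.shape:
        raise ValueError("cusp mask shape mismatch")
    return (volume8.data >= config.calc_threshold_low) & cusp_mask


def calc_volume_fraction(calc_mask: np.ndarray, cusp_mask: np.ndarray) -> float:
    """|calcification| / |cusp| by voxel count, in [0, 1]."""
    calc_mask = np.asarray(calc_mask, dtype=bool)
    cusp_mask = np.asarray(cusp_mask, dtype=bool)
    if calc_mask.shape != cusp_mask.shape:
        raise ValueError("mask shapes differ")
    n_cusp = int(np.count_nonzero(cusp_mask))
    if n_cusp == 0:
        raise ZeroDivisionError("empty cusp mask")
    return int(np.count_nonzero(calc_mask)) / n_cusp


@dataclass
class DensityMasks:
    """Disjoint PVE-corrected density-class masks and their volumes."""

    hd: np.ndarray
    md: np.ndarray
    ld: np.ndarray
    volumes_mm3: dict
    volume_loss_fraction: float
    thresholds: tuple


def pve_decompose(volume8: ImageVolume, cusp_mask: np.ndarray,
                  config: PipelineConfig | None = None) -> DensityMasks:
    """Decompose calcification into density classes with partial-volume correction.

    Protocol, in order:

    1. segment high density (``[high, 255]``) within the cusp;
    2. dilate it by ``hd_dilation_voxels`` and remove the dilated volume
       from the cusp domain (discarding the blurred halo around dense cores);
    3. segment moderate (``[mid, 255]``) then low (``[low, 255]``, minus the
       moderate range) density successively within the reduced domain;
    4. open the moderate and low selections with an ``opening_kernel`` square
       per XY slice;
    5. dilate each of the three selections by
       ``compensation_dilation_voxels`` to give back the volume removed in
       steps 2 and 4.

    After the final dilations, overlaps are resolved with priority
    HD > MD > LD (a dense core is never re-labeled by its halo) and all
    classes are clipped to the cusp. ``volume_loss_fraction`` is the volume
    lost by the correction relative to direct pooled segmentation:
    ``1 - (V_hd + V_md + V_ld) / V_direct`` (0 when there is no
    calcification).
    """
    config = config or PipelineConfig()
    cusp_mask = np.asarray(cusp_mask, dtype=bool)
    if cusp_mask.shape != volume8.data.shape:
        raise ValueError("cusp mask shape mismatch")
    gray = volume8.data
    mode = config.dilation_mode

    hd = (gray >= config.calc_threshold_high) & cusp_mask
    hd_halo = dilate_by_voxels(hd, config.hd_dilation_voxels, mode)
    domain = cusp_mask & ~hd_halo

    md = (gray >= config.calc_threshold_mid) & domain
    ld = (gray >= config.calc_threshold_low) & domain & ~md

    md = open_slicewise(md, config.opening_kernel)
    ld = open_slicewise(ld, config.opening_kernel)

    k = config.compensation_dilation_voxels
    hd = dilate_by_voxels(hd, k, mode) & cusp_mask
    md = dilate_by_voxels(md, k, mode) & cusp_mask & ~hd
    ld = dilate_by_voxels(ld, k, mode) & cusp_mask & ~hd & ~md

    direct = segment_calcification(volume8, cusp_mask, config)
    n_direct = int(np.count_nonzero(direct))
    n_classes = int(np.count_nonzero(hd)) + int(np.count_nonzero(md)) + int(np.count_nonzero(ld))
    loss = 0.0 if n_direct == 0 else 1.0 - n_classes / n_direct

    vox = volume8.voxel_size_um
    volumes = {
        "hd_mm3": mask_volume_mm3(hd, vox),
        "md_mm3": mask_volume_mm3(md, vox),
        "ld_mm3": mask_volume_mm3(ld, vox),
        "direct_mm3": mask_volume_mm3(direct, vox),
    }
    thresholds = (config.calc_threshold_low, config.calc_threshold_mid,
                  config.calc_threshold_high)
    return DensityMasks(hd=hd, md=md, ld=ld, volumes_mm3=volumes,
                        volume_loss_fraction=loss, thresholds=thresholds)
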