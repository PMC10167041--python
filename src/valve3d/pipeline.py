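"""End-to-end quantification of one scan: normalize, segment, decompose, measure."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PipelineConfig
from .cusp_seg import mask_volume_mm3, segment_cusp
from .density_pve import (calc_volume_fraction, pve_decompose,
                          segment_calcification)
from .io_norm import (ImageVolume, ReferenceAnchors, convert_16_to_8,
                      measure_anchor, normalize_to_reference)
from .particles import filter_small, label_particles, particle_metrics
from .report import CuspReport, make_provenance
from .thickness import local_thickness, thickness_summary

__all__ = ["PipelineArtifacts", "quantify_cusp", "quantify_phantom"]


@dataclass
class PipelineArtifacts:
    """Intermediate arrays of one pipeline run, for inspection and testing."""

    normalized: ImageVolume
    cusp_mask: np.ndarray
    calc_mask: np.ndarray
    density_masks: object       # DensityMasks
    particle_labels: np.ndarray
    particle_table: object      # ParticleTable
    thickness_map: object       # ThicknessMap
    anchors: ReferenceAnchors


def quantify_cusp(volume16: ImageVolume,
                  roi_mask: np.ndarray,
                  holder_anchor_mask: np.ndarray,
                  bead_anchor_mask: np.ndarray,
                  ref_anchors: tuple = (20.0, 240.0),
                  config: PipelineConfig | None = None,
                  sample_id: str = "sample",
                  valve_id: str | None = None,
                  group_tag: str = "") -> tuple:
    """Run the full quantification on one 16-bit scan.

    Steps: 16->8 bit conversion with dynamic-range stretch; gray
    normalization onto the reference scale via the holder/bead anchors;
    whole-cusp segmentation within the ROI; calcification segmentation and
    volume fraction; density decomposition with partial-volume correction;
    particle labeling, filtering and morphometry; local-thickness map and
    summary.

    ``ref_anchors`` is (holder mean, bead mean) on the reference gray scale —
    the scale on which the density thresholds are defined.

    Returns ``(CuspReport, PipelineArtifacts)``.
    """
    config = config or PipelineConfig()
    vol8 = convert_16_to_8(volume16, percentile_clip=config.percentile_clip)
    anchors = ReferenceAnchors(
        target_holder=measure_anchor(vol8, holder_anchor_mask),
        target_bead=measure_anchor(vol8, bead_anchor_mask),
        ref_holder=float(ref_anchors[0]),
        ref_bead=float(ref_anchors[1]),
    )
    norm = normalize_to_reference(vol8, anchors)

    cusp = segment_cusp(norm, config, roi_mask=roi_mask)
    cusp_vol = mask_volume_mm3(cusp, norm.voxel_size_um)
    calc = segment_calcification(norm, cusp, config)
    fraction = calc_volume_fraction(calc, cusp)
    density = pve_decompose(norm, cusp, config)

    labels = filter_small(label_particles(calc, config.connectivity),
                          config.min_particle_voxels)
    table = particle_metrics(labels, cusp_vol, norm.voxel_size_um, config)

    tmap = local_thickness(cusp, norm.voxel_size_um)
    tsum = thickness_summary(tmap, thin_threshold_mm=config.thin_threshold_mm,
                             bin_width_mm=config.histogram_bin_width_mm)

    report = CuspReport(
        sample_id=sample_id,
        valve_id=valve_id if valve_id is not None else sample_id,
        group_tag=group_tag,
        cusp_volume_mm3=cusp_vol,
        calc_volume_mm3=mask_volume_mm3(calc, norm.voxel_size_um),
        calc_volume_fraction=fraction,
        density_volumes_mm3=density.volumes_mm3,
        volume_loss_fraction=density.volume_loss_fraction,
        particle_summary=table.summary(),
        thickness_summary=tsum,
        provenance=make_provenance(config, volume16.data),
    )
    artifacts = PipelineArtifacts(
        normalized=norm, cusp_mask=cusp, calc_mask=calc, density_masks=density,
        particle_labels=labels, particle_table=table, thickness_map=tmap,
        anchors=anchors,
    )
    return report, artifacts


def quantify_phantom(spec, config: PipelineConfig | None = None,
                     sample_id: str | None = None, group_tag: str = "") -> tuple:
    """Generate a phantom from its spec and quantify it; returns (report, artifacts, gt)."""
    from .phantom import generate_phantom

    vol16, gt = generate_phantom(spec)
    report, artifacts = quantify_cusp(
        vol16,
        roi_mask=gt.roi_mask,
        holder_anchor_mask=gt.holder_anchor_mask,
        bead_anchor_mask=gt.bead_anchor_mask,
        ref_anchors=(spec.grays.holder, spec.grays.bead),
        config=config,
        sample_id=sample_id or f"phantom-{spec.seed}",
        group_tag=group_tag,
    )
    return report, artifacts, gt
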