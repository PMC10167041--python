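"""Synthetic microCT phantoms of calcified valve cusps with known ground truth.

The phantom emulates what one reconstructed scan contains: a curved
soft-tissue slab (the cusp) carrying spherical calcified inclusions of three
density strata, a high-density borosilicate reference bead and a low-density
sample-holder slab in the field of view, imaged through a Gaussian
point-spread blur with additive Gaussian reconstruction noise, exported as a
16-bit volume. Ground truth (pre-blur masks, per-inclusion volumes, thickness
profile, anchor regions) is captured before any degradation, so every
pipeline stage can be checked against known values.

Default gray levels straddle the protocol's thresholds 25/75/139/197:
background 5, holder 20, soft tissue 45, LD 95, MD 165, HD 220, bead 240.
The default grid is 192 x 192 voxels laterally, 96 axially, at an artificial
voxel size of 50 um so that mm-scale morphometry is exercised at desk scale;
every metric is voxel-size-parametric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .io_norm import ImageVolume, round_half_away

__all__ = [
    "GrayLevels",
    "Inclusion",
    "PhantomSpec",
    "PhantomGroundTruth",
    "generate_phantom",
    "sample_cohort",
    "recovery_phantom_spec",
    "default_group_params",
]

DENSITY_CLASSES = ("ld", "md", "hd")


@dataclass(frozen=True)
class GrayLevels:
    background: float = 5.0
    holder: float = 20.0
    soft_tissue: float = 45.0
    ld: float = 95.0
    md: float = 165.0
    hd: float = 220.0
    bead: float = 240.0

    def __post_init__(self):
        ordered = (self.background, self.holder, self.soft_tissue,
                   self.ld, self.md, self.hd)
        if not all(a < b for a, b in zip(ordered, ordered[1:])):
            raise ValueError("gray levels must satisfy background < holder < "
                             "soft tissue < LD < MD < HD")
        if not all(0 <= v <= 255 for v in asdict(self).values()):
            raise ValueError("gray levels must lie in [0, 255]")

    def for_class(self, density_class: str) -> float:
        return {"ld": self.ld, "md": self.md, "hd": self.hd}[density_class]


@dataclass(frozen=True)
class Inclusion:
    """A spherical (or ellipsoidal) calcified inclusion.

    ``center_vox`` is (z, y, x) in voxel coordinates; ``radius_mm`` gives a
    sphere, or ``semi_axes_mm`` (z, y, x) an axis-aligned ellipsoid.
    """

    center_vox: tuple
    density_class: str
    radius_mm: float | None = None
    semi_axes_mm: tuple | None = None

    def __post_init__(self):
        if self.density_class not in DENSITY_CLASSES:
            raise ValueError(f"unknown density class {self.density_class!r}")
        if (self.radius_mm is None) == (self.semi_axes_mm is None):
            raise ValueError("specify exactly one of radius_mm or semi_axes_mm")


@dataclass
class PhantomSpec:
    """Complete description of one synthetic scan. ``seed`` is mandatory."""

    seed: int
    shape: tuple = (96, 192, 192)            # (z, y, x)
    voxel_size_um: float = 50.0
    base_thickness_mm: float = 1.5
    nodule_thickness_mm: float | None = None  # local thickening (e.g. around a large nodule)
    nodule_center_yx: tuple | None = None
    nodule_radius_mm: float | None = None
    curvature_radius_mm: float | None = 20.0  # cylinder radius of the bent slab; None = flat
    lateral_margin_vox: int = 16
    slab_bottom_vox: int = 16
    inclusions: tuple = ()
    grays: GrayLevels = field(default_factory=GrayLevels)
    psf_sigma_voxels: float = 1.0
    noise_sigma: float = 2.0
    holder_height_vox: int = 6
    bead_center_vox: tuple = (80, 184, 184)
    bead_radius_vox: float = 7.0
    roi_margin_vox: int = 4

    def voxels_per_mm(self) -> float:
        return 1000.0 / self.voxel_size_um


@dataclass
class PhantomGroundTruth:
    """Pre-blur truth for one phantom."""

    cusp_mask: np.ndarray
    roi_mask: np.ndarray
    holder_anchor_mask: np.ndarray
    bead_anchor_mask: np.ndarray
    inclusion_labels: np.ndarray             # 0 background, i >= 1 per inclusion
    inclusion_classes: tuple                 # density class per inclusion (id order)
    inclusion_voxel_counts: tuple
    calc_volume_fraction: float
    thickness_profile_vox: np.ndarray        # per-(y, x) column voxel count of the cusp
    mean_thickness_mm: float                 # volume-weighted over cusp columns
    class_voxel_totals: dict                 # 'ld'/'md'/'hd' -> voxel count
    voxel_size_um: float

    def inclusion_mask(self, i: int) -> np.ndarray:
        return self.inclusion_labels == i

    @property
    def calc_mask(self) -> np.ndarray:
        return self.inclusion_labels > 0


def _ellipsoid_mask(shape, center, semi_axes_vox) -> np.ndarray:
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    az, ay, ax = semi_axes_vox
    d = (((zz - center[0]) / az) ** 2 + ((yy - center[1]) / ay) ** 2
         + ((xx - center[2]) / ax) ** 2)
    return d <= 1.0


def _slab_geometry(spec: PhantomSpec):
    """Bottom surface z_b(y) and thickness t(y, x) of the curved slab, in voxels."""
    nz, ny, nx = spec.shape
    vpm = spec.voxels_per_mm()
    m = spec.lateral_margin_vox
    y = np.arange(ny, dtype=np.float64)
    if spec.curvature_radius_mm is not None:
        rc = spec.curvature_radius_mm * vpm
        yc = (ny - 1) / 2.0
        off = np.clip(np.abs(y - yc), 0, rc)
        sag = rc - np.sqrt(rc * rc - off * off)
    else:
        sag = np.zeros(ny)
    z_bottom = spec.slab_bottom_vox + sag                      # per y
    t = np.full((ny, nx), spec.base_thickness_mm * vpm)
    if spec.nodule_thickness_mm is not None:
        if spec.nodule_center_yx is None or spec.nodule_radius_mm is None:
            raise ValueError("nodule thickness given without center/radius")
        cy, cx = spec.nodule_center_yx
        yy, xx = np.mgrid[:ny, :nx]
        nod = (yy - cy) ** 2 + (xx - cx) ** 2 <= (spec.nodule_radius_mm * vpm) ** 2
        t[nod] = spec.nodule_thickness_mm * vpm
    footprint = np.zeros((ny, nx), dtype=bool)
    footprint[m:ny - m, m:nx - m] = True
    t[~footprint] = 0.0
    return z_bottom, t


def _build_ground_truth(spec: PhantomSpec) -> PhantomGroundTruth:
    nz, ny, nx = spec.shape
    z_bottom, t = _slab_geometry(spec)
    zz = np.arange(nz, dtype=np.float64)[:, None, None]
    zb = z_bottom[None, :, None]
    cusp = (zz >= zb) & (zz < zb + t[None, :, :])
    if not cusp.any():
        raise ValueError("phantom spec produces an empty cusp")

    if (z_bottom.min() < spec.holder_height_vox + 2):
        raise ValueError("slab bottom overlaps or touches the sample holder")
    if float((zb + t[None, :, :]).max()) > nz - 2:
        raise ValueError("slab extends past the top of the volume")

    vpm = spec.voxels_per_mm()
    labels = np.zeros(spec.shape, dtype=np.int16)
    classes, counts = [], []
    for i, inc in enumerate(spec.inclusions, start=1):
        if inc.radius_mm is not None:
            semi = (inc.radius_mm * vpm,) * 3
        else:
            semi = tuple(a * vpm for a in inc.semi_axes_mm)
        mask = _ellipsoid_mask(spec.shape, inc.center_vox, semi)
        if not mask.any():
            raise ValueError(f"inclusion {i} is smaller than one voxel")
        if (mask & ~cusp).any():
            raise ValueError(f"inclusion {i} ({inc.density_class}) is not inside the cusp")
        if (labels[mask] != 0).any():
            raise ValueError(f"inclusion {i} overlaps a previous inclusion")
        labels[mask] = i
        classes.append(inc.density_class)
        counts.append(int(mask.sum()))

    class_totals = {c: 0 for c in DENSITY_CLASSES}
    for c, n in zip(classes, counts):
        class_totals[c] += n

    profile = cusp.sum(axis=0)
    col = profile[profile > 0].astype(np.float64)
    mean_thick_mm = float((col ** 2).sum() / col.sum()) / vpm

    # ROI: everything except the holder and the bead neighborhoods
    roi = np.ones(spec.shape, dtype=bool)
    roi[: spec.holder_height_vox + spec.roi_margin_vox] = False
    bz, by, bx = spec.bead_center_vox
    br = spec.bead_radius_vox + spec.roi_margin_vox
    bead_ball = _ellipsoid_mask(spec.shape, (bz, by, bx), (br, br, br))
    roi &= ~bead_ball
    if (cusp & ~roi).any():
        raise ValueError("cusp extends outside the region of interest")

    holder_anchor = np.zeros(spec.shape, dtype=bool)
    holder_anchor[1:max(2, spec.holder_height_vox - 3),
                  ny // 2 - 10: ny // 2 + 10, nx // 2 - 10: nx // 2 + 10] = True
    r_in = max(1.0, spec.bead_radius_vox - 3)
    bead_anchor = _ellipsoid_mask(spec.shape, spec.bead_center_vox, (r_in,) * 3)

    n_cusp = int(cusp.sum())
    return PhantomGroundTruth(
        cusp_mask=cusp,
        roi_mask=roi,
        holder_anchor_mask=holder_anchor,
        bead_anchor_mask=bead_anchor,
        inclusion_labels=labels,
        inclusion_classes=tuple(classes),
        inclusion_voxel_counts=tuple(counts),
        calc_volume_fraction=float(sum(counts)) / n_cusp,
        thickness_profile_vox=profile,
        mean_thickness_mm=mean_thick_mm,
        class_voxel_totals=class_totals,
        voxel_size_um=spec.voxel_size_um,
    )


def generate_phantom(spec: PhantomSpec) -> tuple:
    """Render a 16-bit phantom volume and its pre-blur ground truth.

    Rendering order: background, holder slab, bead sphere, cusp slab,
    inclusions — each at its gray level — then Gaussian PSF blur, seeded
    additive Gaussian noise, clamping to [0, 255] and scaling to 16-bit
    (x 257). Deterministic given ``spec.seed``.
    """
    if spec.seed is None:
        raise ValueError("spec.seed is mandatory")
    gt = _build_ground_truth(spec)
    g = spec.grays
    nz, ny, nx = spec.shape

    canvas = np.full(spec.shape, g.background, dtype=np.float64)
    canvas[: spec.holder_height_vox] = g.holder
    bead = _ellipsoid_mask(spec.shape, spec.bead_center_vox, (spec.bead_radius_vox,) * 3)
    canvas[bead] = g.bead
    canvas[gt.cusp_mask] = g.soft_tissue
    for i, cls in enumerate(gt.inclusion_classes, start=1):
        canvas[gt.inclusion_labels == i] = g.for_class(cls)

    if spec.psf_sigma_voxels > 0:
        canvas = ndimage.gaussian_filter(canvas, sigma=spec.psf_sigma_voxels)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        canvas = canvas + rng.normal(0.0, spec.noise_sigma, size=canvas.shape)
    canvas = np.clip(canvas, 0.0, 255.0)
    vol16 = np.asarray(round_half_away(canvas * 257.0), dtype=np.uint16)
    return ImageVolume(vol16, spec.voxel_size_um), gt


def recovery_phantom_spec(seed: int) -> PhantomSpec:
    """Controlled parameter-recovery phantom: three well-separated single-density spheres.

    The partial-volume protocol carries two systematic biases that constrain
    the layout (derivation in docs/methods.md): the final 1-voxel cubic
    dilation inflates every class by roughly 1.3 voxels of radius, so a class
    volume is only recoverable within ~15% when dominated by an inclusion
    tens of voxels across; and the blurred rim of a moderate-density particle
    crosses the low-density gray range — the opening removes the thin rim
    annulus but not its polar caps, so MD surface area leaks into the LD
    class (the HD halo, in contrast, is explicitly removed by the protocol).
    Hence one large sphere per class — LD r=36, MD r=16, HD r=10 voxels — in
    a 2.4 mm slab with a 4 mm nodule hosting the LD sphere. Surface
    separations exceed 17 voxels; PSF sigma = 1 voxel, noise sigma = 2 gray
    levels.
    """
    mm = 0.05  # mm per voxel at 50 um
    return PhantomSpec(
        seed=seed,
        shape=(96, 192, 192),
        voxel_size_um=50.0,
        base_thickness_mm=48 * mm,
        nodule_thickness_mm=80 * mm,
        nodule_center_yx=(96, 96),
        nodule_radius_mm=44 * mm,
        curvature_radius_mm=None,
        slab_bottom_vox=12,
        inclusions=(
            Inclusion(center_vox=(52, 96, 96), density_class="ld", radius_mm=36 * mm),
            Inclusion(center_vox=(36, 48, 48), density_class="md", radius_mm=16 * mm),
            Inclusion(center_vox=(36, 140, 140), density_class="hd", radius_mm=10 * mm),
        ),
        psf_sigma_voxels=1.0,
        noise_sigma=2.0,
    )


def default_group_params() -> dict:
    """Two-group study conditions contrasting a mildly and a heavily calcified cohort.

    Group A (NF-LG-SAS-like): thinner cusp, fewer and smaller inclusions.
    Group B (HG-SAS-like): thicker cusp, more and larger inclusions.
    Both imaged identically (PSF sigma 1 voxel, noise sigma 2 gray levels)
    on a 128 x 128 x 64 grid at 50 um.
    """
    common = dict(shape=(64, 128, 128), voxel_size_um=50.0,
                  curvature_radius_mm=20.0, lateral_margin_vox=14,
                  slab_bottom_vox=12, bead_center_vox=(48, 120, 120),
                  bead_radius_vox=5.0, psf_sigma_voxels=1.0, noise_sigma=2.0)
    return {
        "A": dict(common, base_thickness_mm=1.2,
                  n_inclusions_range=(3, 6), radius_range_vox=(3.0, 7.0)),
        "B": dict(common, base_thickness_mm=1.8,
                  n_inclusions_range=(8, 14), radius_range_vox=(4.0, 10.0)),
    }


def _place_inclusions(rng, params) -> tuple:
    """Rejection-sample non-overlapping spheres inside the slab (surface gap >= 5 voxels)."""
    shape = params["shape"]
    vpm = 1000.0 / params["voxel_size_um"]
    t_vox = params["base_thickness_mm"] * vpm
    m = params["lateral_margin_vox"]
    lo_n, hi_n = params["n_inclusions_range"]
    lo_r, hi_r = params["radius_range_vox"]
    n = int(rng.integers(lo_n, hi_n + 1))
    placed = []   # (center, radius_vox)
    inclusions = []
    # curvature sag over the footprint (keep z placement safely inside the slab)
    if params.get("curvature_radius_mm") is not None:
        rc = params["curvature_radius_mm"] * vpm
        half = (shape[1] - 1) / 2.0 - m
        sag_max = rc - math.sqrt(rc * rc - half * half)
    else:
        sag_max = 0.0
    for _ in range(n):
        r = float(rng.uniform(lo_r, hi_r))
        r = min(r, t_vox / 2.0 - 3.0)
        if r < 2.0:
            continue
        for _attempt in range(200):
            y = float(rng.uniform(m + r + 3, shape[1] - m - r - 3))
            x = float(rng.uniform(m + r + 3, shape[2] - m - r - 3))
            zc = params["slab_bottom_vox"] + sag_max + t_vox / 2.0
            c = (zc, y, x)
            if all(math.dist(c, pc) >= r + pr + 5.0 for pc, pr in placed):
                placed.append((c, r))
                cls = DENSITY_CLASSES[int(rng.integers(0, 3))]
                inclusions.append(Inclusion(center_vox=c, density_class=cls,
                                            radius_mm=r / vpm))
                break
    return tuple(inclusions)


def sample_cohort(n_per_group: int, group_params: dict | None = None,
                  seed: int = 0) -> list:
    """Reproducible two-group cohort of phantom specs.

    Returns a list of ``(PhantomSpec, group_tag)``. Group differences
    (inclusion count and size distribution, slab thickness) are controlled by
    ``group_params`` (see :func:`default_group_params`).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    group_params = group_params or default_group_params()
    master = np.random.default_rng(seed)
    cohort = []
    for tag in sorted(group_params):
        params = group_params[tag]
        for _ in range(n_per_group):
            sub_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(sub_seed)
            inclusions = _place_inclusions(rng, params)
            spec_kwargs = {k: v for k, v in params.items()
                           if k not in ("n_inclusions_range", "radius_range_vox")}
            cohort.append((PhantomSpec(seed=sub_seed, inclusions=inclusions,
                                       **spec_kwargs), tag))
    return cohort
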