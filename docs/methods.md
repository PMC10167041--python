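# Methods

This note records the models, numeric conventions and design choices behind
the pipeline, and what validation on synthetic phantoms does and does not
establish.

## Gray scales and normalization

Reconstructed volumes arrive as 16-bit XY slice stacks with arbitrary gray
scaling. Conversion to 8 bits maps the dataset minimum to 0 and maximum to
255 (strict min/max by default; a percentile clip is available in
`PipelineConfig.percentile_clip` for datasets with outlier voxels, off by
default). Every re-quantization of gray values rounds half away from zero.

Datasets are then mapped onto a common reference scale by the unique affine
gray map sending the measured (holder mean, bead mean) of the dataset to the
reference's pair. Anchor regions are supplied as masks — drawn manually on
real scans, emitted programmatically by the phantom generator. The two
anchor materials bracket the gray range of interest (holder below soft
tissue, bead above high-density mineral), so the affine map is
well-conditioned; composition of affine maps keeps re-measured anchors
within ±1 gray of the reference, the tolerance asserted in the tests. All
density thresholds (25, 75, 139, 197) are defined on this reference scale.
No Hounsfield or mineral-density calibration is attempted: gray values are
relative, which is sufficient for within-study comparisons.

## Whole-cusp segmentation

The cusp (soft tissue plus mineral) is gray ∈ [25, 255] within an externally
supplied region of interest that excludes holder and bead, followed by
closing with a 5×5 square applied per XY slice. "Square" kernels are 2D and
slice-wise, matching the naming convention of slice-oriented CT analysis
tools; a cubic 3D alternative is exposed via `closing_3d`. Closing is
computed on the infinite domain (the array is padded by the kernel radius
first), so a structure touching the scan border is not eroded by border
handling. Threshold bounds are inclusive at both ends.

## Multilevel Otsu

`multilevel_otsu` takes a 256-bin histogram — computed over cusp voxels
only, since background air would otherwise dominate the class variance —
and returns the n thresholds maximizing between-class variance. With
interval contribution S(a,b)²/W(a,b) (W = count, S = gray-weighted count;
empty intervals contribute 0), the optimum over partitions is found by an
exact dynamic program over the 257×257 interval table, O(n·L²). Each
threshold is the lowest gray value of its upper class, so a threshold of 75
means "calcified" is 75 and up. Ties are broken toward the
lexicographically smallest tuple; `valve3d.reference.exhaustive_multiotsu`
enumerates all increasing tuples flatly and the test suite asserts equality
on random histograms. "3 levels" means 3 thresholds / 4 classes: soft
tissue plus three density strata.

## Partial-volume correction

The point-spread function smears every density step over ~±2σ, so rim
voxels of a dense particle take intermediate gray values and would be
assigned to a lower density class. The correction protocol is executed
verbatim in this order: segment HD ([197, 255]) in the cusp; dilate it by
2 voxels and remove the dilated set from the domain; segment MD
([139, 255]) then LD ([75, 255] minus the MD range) in the reduced domain;
open MD and LD with a 2×2 square per XY slice; dilate all three selections
by 1 voxel. "Dilation by k voxels" is k iterations of the 3×3×3 cube
(Chebyshev ball) by default; a Euclidean (6-connected) alternative is
config-switchable. Opening is invariant to the structuring-element anchor,
so the even kernel is unambiguous. After the final dilation, overlaps
resolve with priority HD > MD > LD (a dense core is never re-labeled by its
halo) and classes are clipped to the cusp. The volume-loss fraction
1 − (V_hd + V_md + V_ld)/V_direct is reported per sample; it is negative
when the compensation dilation regains more than the halo removal took,
which is the expected regime for isolated single-density particles.

Two systematic biases of this protocol matter for interpretation, and they
set the validity regime of the recovery tests:

1. **Dilation overshoot.** For an isolated particle of radius r voxels, the
   corrected class volume is approximately the segmented particle dilated
   by one cubic voxel — an effective radial gain of ~1.3–1.5 voxels minus
   the blur-induced segmentation erosion (≈1.1σ for HD, 0.8σ for MD,
   0.25σ for LD at contrast against soft tissue). Relative volume error
   therefore scales as ~3·Δr/r: a 15% class-volume recovery needs the class
   dominated by particles tens of voxels across. Small particles are
   over-estimated substantially (an r = 3 HD sphere roughly doubles).
2. **MD rim leakage into LD.** The blurred rim of a moderate-density
   particle crosses the LD gray range in a shell ≈1.45σ thick. The 2×2
   opening removes this shell where slices cut it as a thin annulus, but at
   the particle's poles the slices cut filled disks, which survive. The
   protocol removes the HD halo explicitly (the dilate-by-2 step) but has
   no analogous protection for MD rims, so LD volume inherits a
   contribution proportional to total MD surface area.

## Particles

Calcified particles are connected components of the pooled calcification
mask. The adjacency rule of the original labeling tool is undocumented;
default is 26-connectivity with 6 and 18 available, and the choice is
recorded in the report. Component ids are assigned in raster-scan order of
each component's first voxel, making labelings reproducible and directly
comparable to the flood-fill reference. Particles of ≤ 10 voxels are
discarded (boundary inclusive). Size classes by physical volume: micro
≤ 10⁻³ mm³, macro ≥ 1 mm³, meso between — micro closed above and macro
closed below; class boundaries carry a 10⁻⁹ relative tolerance so volumes
computed as count × voxel-volume classify correctly at the boundary. At
14 µm voxels the boundaries are 364.4 and 364 431 voxels (recorded in the
report); at the phantom's 50 µm they are 8 and 8000 voxels — note that
8 ≤ 10 means no microscale particle survives the filter at 50 µm.
`particles_per_mm3` normalizes by the entire-cusp volume, the only
per-sample volume defined.

## Local thickness

Thickness at p is the diameter of the largest sphere containing p and
fitting in the structure. Digital convention (normative for implementation
and oracle alike): with R(q) the Euclidean distance from voxel q to the
nearest background voxel center (outside the array is background), the
sphere at q covers voxels with |p − q| < R(q) — exactly its foreground
voxels — and has diameter 2(R(q) − 0.5). The half-voxel term places the
boundary between the last foreground and first background voxel, so a slab
of 9 voxels measures 9 voxels thick (even-thickness slabs measure t − 1,
the unavoidable half-voxel ambiguity of voxel-center sampling). All
comparisons are on squared integer distances, so the computation is exact:
squared EDT, pruning of spheres provably contained in a neighbor's sphere
(an exact, transitive containment test — pruning affects speed only),
then sphere painting in descending radius order. The brute-force reference
paints every voxel's maximal sphere with no pruning. Mean thickness of
digital balls of diameter 8–24 voxels lands within 10% of the nominal
diameter (worst case ≈9.4% at diameter 8, from the lattice gap between the
largest inscribed radius and the nominal radius).

Summaries are volume-weighted over mask voxels: mean, histogram of volume
proportion per thickness bin (0.1 mm default width), and the fraction
strictly below the thin threshold (0.7 mm default — the mean thickness of
a non-calcified cusp). A structure touching the scan border is thin there
by convention; the lateral rim of any finite slab is genuinely thin, which
is physically sensible for excised samples but means idealized
"infinite slab" statements hold on interior columns.

## Synthetic phantoms

The generator emulates one reconstructed scan: a bent soft-tissue slab
(section of a cylindrical shell; curvature radius 20 mm by default, large
enough that radial and axial thickness agree to <1%), spherical
single-density inclusions, a sample-holder slab and a borosilicate-like
bead, rendered at gray levels background 5, holder 20, soft tissue 45,
LD 95, MD 165, HD 220, bead 240 — chosen to straddle the protocol
thresholds 25/75/139/197 — then blurred with a Gaussian PSF (σ = 1 voxel
default), degraded with additive Gaussian noise (σ = 2 gray levels
default), and scaled to 16 bits. Ground truth (pre-blur masks, per-inclusion
volumes and classes, thickness profile, anchor and ROI masks) is captured
before degradation, and generation is deterministic given the
`PhantomSpec` seed.
The default grid is 192×192×96 at an artificial 50 µm voxel size so that
mm-scale morphometry runs at desk scale; every metric is
voxel-size-parametric.

What the phantom does **not** model: beam hardening, ring artifacts,
projection/reconstruction noise correlations (noise is i.i.d. additive),
anatomical cusp geometry (free/adherent edges), mixed-density particles
with nested strata, and sub-voxel mineral texture. Passing recovery tests
therefore demonstrates the correctness of the measurement chain under
controlled degradation, not robustness to scanner physics.

The controlled recovery phantom (`recovery_phantom_spec`) places one large
sphere per density class — LD r = 36, MD r = 16, HD r = 10 voxels — in a
2.4 mm slab with a 4 mm nodule hosting the LD sphere, all surface
separations > 17 voxels. The sizes follow directly from the two bias
mechanisms above: each class must be dominated by a particle large enough
that the ~1-voxel radial overshoot stays within 15%, while MD surface area
is kept small because it leaks into LD. With this geometry the measured
class-volume errors are ≈14% (LD), ≈12% (MD), ≈9% (HD), stable to ±0.3%
across noise seeds.

The cohort generator (`sample_cohort`) contrasts a mild group A
(slab 1.2 mm; 3–6 inclusions of radius 3–7 voxels) with a severe group B
(slab 1.8 mm; 8–14 inclusions of radius 4–10 voxels), density classes
assigned uniformly, positions rejection-sampled with ≥5-voxel surface
gaps, on a 128×128×64 grid. These conditions produce the expected ordering
of calcified fraction, small-particle count and mean thickness between
groups, which the cohort sanity test asserts on group means (n = 10 per
group).

## Statistics

Mann-Whitney U: for combined n ≤ 20 the two-sided p is exact — the
permutation distribution of U is enumerated by a dynamic program over
doubled midranks (integers, so tail comparisons are exact), and
p = P(|U − n₁n₂/2| ≥ |u_obs − n₁n₂/2|). This reduces to the familiar
doubled tail in the untied case and handles ties without approximation;
above n = 20 the normal approximation with tie correction is used and the
method is recorded. Correlations are Pearson or Spearman with t-based
two-sided p; the method is an explicit argument (no automated normality
gate). Valve-level aggregation pools cusp volumes (Σ calc / Σ cusp), so
the valve fraction lies between its cusps' fractions. Significance stars
follow the *, **, ***, **** convention at 0.05/0.01/0.001/0.0001; no
multiple-testing correction is applied, and p-values are always reported
numerically alongside the stars.

## Numerical conventions, degenerate inputs

- Rounding: half away from zero wherever gray values are quantized.
- Constant 16-bit volume → degenerate-range error; equal anchors →
  degenerate-anchor error; histogram with fewer occupied bins than classes
  → degenerate-histogram error; empty cusp → division error; empty
  thickness map → input error.
- Empty masks are valid inputs to labeling/filtering and yield empty
  outputs; volume-loss fraction is defined as 0 when no calcification is
  directly segmented.
- The problem sizes used throughout validation — 40³ oracle masks,
  a 192×192×96 recovery phantom, 128×128×64 cohort phantoms, n = 10 per
  group — are the package's chosen desk-scale study conditions.

## Known limitations

- Gray thresholds are scale-bound: applying 75/139/197 presumes successful
  normalization onto the reference scale.
- The PVE protocol's accuracy is size- and composition-dependent (see the
  two bias mechanisms above); per-class volumes for samples dominated by
  small or thin-shelled particles carry larger systematic error than the
  recovery phantom suggests.
- Even-thickness structures measure one voxel thin; thickness of structures
  at the scan border reflects the border-as-background convention.
- ROI and anchor masks are inputs, not outputs: automatic holder/bead
  detection is out of scope.
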