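# Methods

This note documents the models, conventions and numerical choices behind
`btvseg`, and what the synthetic phantoms do and do not establish about
behaviour on real patient data.

## Imaging model and conventions

A volume is a regular 3-D voxel grid embedded in world space: shape,
per-axis spacing (mm), origin (world position of the centre of voxel
(0,0,0)) and an orthonormal direction-cosine matrix.  World coordinates
are millimetres in the LPS convention (DICOM's patient system); NIfTI
affines, which are RAS, are converted by negating the first two world
axes on read/write, so NIfTI round trips are bit-exact on voxels and
agree on the affine to float precision.

A voxel is represented by its centre: masks are centre-in/centre-out with
no fractional voxels, and `volume_ml = count × prod(spacing)/1000`.  This
matches how clinical systems count VOI volumes and makes every volume
statement exactly testable.  Consequences worth knowing:

* **Sphere rasterization** keeps a voxel iff its centre lies within the
  radius; on a 2 mm grid a 15 ml sphere rasterizes within a few percent
  of its analytic volume, on a 4 mm PET grid within ~15%.
* **Mask resampling** is nearest-neighbour only (preserves binarity):
  each target voxel takes the value of the source voxel whose centre is
  nearest in world space; target voxels outside the source extent are
  background, and fully non-overlapping grids produce a warning plus an
  empty mask rather than an error.  Back-projecting a PET-grid VOI onto
  a CT grid whose spacing divides the PET spacing conserves volume
  exactly; in general the error is bounded by about one PET voxel.

SUV is the body-weight convention, `SUV = activity [kBq/ml] × weight [kg]
/ dose [MBq]` with tissue density taken as 1 g/ml.  Body-weight SUV is
assumed throughout (lean-body-mass and BSA variants are deliberately out
of scope).

## Segmentation algorithms

All five algorithms share one structure: find the SUV_max voxel inside a
caller-supplied **search region**, threshold, and keep the connected
component containing that seed (region growing).  Design choices:

* The search region must be supplied (box or mask).  Lesion VOIs are
  placed interactively in clinical practice; an unguided whole-body
  search would latch onto brain or bladder uptake.  Percent thresholds
  are relative to the *region's* SUV_max — lesion-wise, not image-wise —
  so adjacent hot organs do not shift the threshold.
* Threshold comparison is inclusive (≥), guaranteeing the seed always
  qualifies; ties at SUV_max resolve to the lowest lexicographic voxel
  index, making results deterministic.
* Connectivity for region growing is 26-neighbour by default
  (configurable 6/18/26); 26 avoids fragmenting thin diagonal structures
  at PET resolution.
* Segmentation runs on the native PET grid and is back-projected to the
  CT grid afterwards; all agreement metrics are computed on the CT grid.

The PERCIST-TLG boundary is `liver mean + k × liver SD` with `k = 3` by
default, the statistics taken over a rasterized 15 ml sphere (the
conventional background VOI shape) with the sample SD (n−1).  Note that
this differs from the published PERCIST 1.0 threshold
(1.5 × liver mean + 2 SD); the mean + 3 SD form is implemented as the
default on purpose and `k` is configurable — the multiplier is not
silently "corrected".  A lesion whose SUV_max falls below the background
threshold is a legitimate PET-negative finding: the algorithm returns an
empty mask and a `LesionNotAboveBackgroundWarning`, never an exception.

Structures with high physiologic uptake abutting the tumour can be
removed with `exclude_structures` (set difference), mirroring the manual
masking step such lesions need in practice.

## Agreement metrics

The conformity index is 100 × |A∩B|/|A∪B| (Jaccard × 100), symmetric, and
never exceeds either inclusion ratio or the Dice coefficient.  Because
the direction of a single "inclusion ratio" is chronically ambiguous in
the literature, `compare_pair` always reports both |∩|/|BTV| and
|∩|/|GTV| explicitly.  Empty-denominator cases yield 0 with a
`both_empty` flag rather than NaN.  Tables render percentages to one
decimal place; full precision is kept internally.

## Wilcoxon signed-rank test

Volumes in small planning cohorts are not normally distributed, so BTV vs
GTV volumes are compared with the paired two-tailed Wilcoxon signed-rank
test at α = 0.05, with no multiple-comparison correction (the summary is
descriptive, one table per cohort).  Implementation details:

* zero differences are dropped (classical reduction, not Pratt);
  absolute differences are ranked with average ranks for ties; the
  reported statistic is W = min(W⁺, W⁻);
* for n_effective ≤ 25 the two-sided p is exact: the null distribution
  of W⁺ conditional on the observed ranks is built by convolution over
  the rank multiset (ranks doubled to keep tie-averaged half-ranks
  integral), which is identical to enumerating all 2ⁿ sign assignments;
  p = P(W⁺ ≤ W) + P(W⁺ ≥ W_total − W), capped at 1;
* for larger n a normal approximation with continuity correction and the
  standard tie correction (Σ(t³−t)/48 subtracted from the variance) is
  used; the switch point 25 keeps the exact path cheap while covering
  any cohort of the size this methodology targets;
* the degenerate all-zero-difference case reports p = 1, n_effective = 0
  and a flag.

Tests verify the exact path against literal 2ⁿ enumeration (n ≤ 12),
against an independent library implementation on tie-free data, and
calibration: the null rejection rate over 2000 simulated n = 20 cohorts
falls in [0.03, 0.07] (the exact test is slightly conservative by
discreteness, ~0.049 observed).

## Synthetic phantoms

`PhantomSpec` describes one synthetic patient; the defaults encode the
study conditions the pipeline is rehearsed under:

| parameter | default | rationale |
|---|---|---|
| PET grid | 4 mm isotropic, 192 mm FOV | typical whole-body PET resolution |
| CT grid | 2 mm isotropic, same FOV | planning-CT scale |
| lesion peak SUV | log-normal, median 9.2, clipped 3.1–18.2 | observed SUV_max range in comparable cohorts |
| background SUV | 1.0 | soft-tissue uptake |
| liver compartment | ellipsoid, mean SUV 2.0, SD 0.3 | normal hepatic uptake; hosts the 15 ml PERCIST VOI |
| PSF FWHM | 7 mm | clinical PET partial-volume blur |
| noise SD | 0.2 SUV | additive post-reconstruction noise scale |
| GTV error | +3 mm dilation, 1.5 mm warp (cohort default) | manual GTVs tend to exceed true tumour extent |

Generation order: paint the ideal SUV field (background, liver Gaussian
texture, lesion at peak), blur with the Gaussian PSF, add Gaussian noise,
clip at zero.  Noise is additive Gaussian on the blurred SUV field rather
than Poisson on counts: the artifact tests segmentation logic, not
reconstruction physics (a count-domain Poisson mode would be a natural
extension).  All randomness flows from a single seed; each phantom
records its spec for provenance, and a fixed spec regenerates
bit-identical output.

Two truth masks are carried: the pre-blur lesion support on the PET grid
(what a PET-grid segmentation can recover exactly) and the analytic
raster on the CT grid (from which the simulated manual GTV is derived).
The "manual" GTV is the CT-grid truth shifted by a signed-distance offset
in mm (positive = oversized contour) plus a smooth random warp of the
boundary, with zero error reproducing the CT truth exactly.

Cohorts allocate sites by deterministic largest remainder (20 patients at
40/25/35% gives exactly 8 lung / 5 oesophageal / 7 pelvic) with site
presets: lung = medium spheres (14–22 mm radius), oesophageal = small
elongated ellipsoids, pelvic = large ellipsoids.

**What phantom results do and do not show.**  Passing tests establish the
*internal* correctness of the pipeline: thresholds are applied exactly,
nested volumes are nested, metrics match brute-force oracles, the
statistics are calibrated.  The phantoms deliberately omit heterogeneous
tracer uptake, respiratory motion, reconstruction artefacts, misaligned
PET/CT, post-chemotherapy tissue change and inter-observer contouring
variability — so phantom conformity indices (typically 45–85% here) say
nothing about the much lower GTV/BTV concordance seen on real patients,
and no clinical claim is made from them.

## Problem sizes and tolerances

Default rehearsal sizes — 20-patient cohorts, 50-phantom nestedness
sweeps, 2000 null simulations, 100 oracle mask pairs, 20 round-trip
shapes — were chosen as the package's standard desk-scale configuration;
each completes in seconds to a couple of minutes on one CPU.  Numerical
tolerances: orthonormality of direction matrices to 1e-6; geometry
equality to 1e-6 mm; RTSTRUCT vertices round-trip within 1e-3 mm;
overlap metrics match set oracles to 1e-12 relative.  On a blurred noisy
15 mm-radius sphere (peak 10, background 1) the 42–50% thresholds land
within ±30% of the true volume — a partial-volume regression bound, not a
clinical accuracy claim; 38% can overshoot further, which is exactly the
behaviour that motivates background-adaptive thresholds.

## Contour and RTSTRUCT conventions

Mask-to-contour extraction traces voxel edges — the 0.5 iso-level of the
binary field under the voxel-centre convention — producing closed planar
polygons per axial slice with outer boundaries counter-clockwise, holes
as separate clockwise polygons (no keyhole technique), and implicit
closure (first vertex not repeated).  Rasterization applies the even-odd
rule to voxel centres.  Because contours run along voxel edges, every
voxel centre is at least half a voxel away from the polygon and
mask → contours → mask round trips are exact; at checkerboard corners the
tracer takes the left turn (in-plane foreground treated 4-connected) so
polygons never self-intersect.  The RTSTRUCT dialect is one ROI per
structure with CLOSED_PLANAR contours in LPS mm; interoperability is
asserted against this package's own reader plus these documented
conventions, not against any vendor dialect.

## Known limitations

* No registration: PET and CT are assumed co-registered (hybrid
  acquisition); only resampling between aligned grids is provided.
* No gradient-based, watershed or adaptive-iterative segmentation
  methods; no automatic liver localization (the background VOI centre is
  supplied by the user or the phantom).
* Axial-identity orientation is required for contour extraction; oblique
  grids must be resampled first.
* The schematic CT exists to carry the planning grid and visual context;
  it has no realistic texture and is not used by any algorithm.
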