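# Methods

This note documents the measurement models, the numerical choices behind
them, and what the synthetic validation does and does not establish.

## Coordinate conventions

World coordinates are RAS millimetres throughout. Voxel indices are
0-based and a voxel's world position is its centre. NIfTI inputs are
reoriented to the closest RAS-canonical axis order on load (a pure
permutation/flip of grid axes — never a resample). Slicer markups in the
LPS dialect have x and y negated on read. Every downstream computation
goes through the voxel↔world affine, so obliquely oriented grids are
handled exactly; all metrics are invariant under a rigid transformation
applied jointly to the label grid's affine and the landmarks.

## Image-quality metrics

The entropy focus criterion treats the ROI intensities as a distribution
normalised by their energy: `E = −Σ (x_j/x_max) ln(x_j/x_max)` with
`x_max = sqrt(Σ x_j²)` and `0·ln 0 := 0`. We report `EFC = E/(√n ln √n)`,
i.e. E over its maximum, so the score is scale-invariant and bounded in
[0, 1]: 1 for a perfectly uniform ROI, 0 for a single bright voxel. The
natural logarithm is used throughout. Within a cohort the *relative*
position of a scan's EFC is what matters; motion artefact (ghosting,
blurring) spreads energy and moves the score.

SNR is the ROI mean over the population SD of an air mask; CNR subtracts
a comparison-region mean first. `make_masks` builds the three regions:
ROI = the structure's voxels; comparison = a morphological dilation of
the ROI (default 3 voxels, 26-connected) minus the ROI and minus every
labelled tissue; background = voxels within 5 voxels of the volume faces,
restricted — when an intensity image is available — to the dark class
under an Otsu threshold. The threshold is only applied when it genuinely
separates two classes (inter-class distance > 3× the pooled within-class
SD): thresholding a unimodal pure-air margin would truncate the noise
distribution and bias σ low by ~40%.

Cohort screening flags values at least 2 population SDs from the mean
(inclusive). With the *sample* SD the largest attainable deviation in a
cohort of n is (n−1)/√n SDs — under 2 for n ≤ 5 — so a single corrupted
scan among five could never be flagged; the population-SD inclusive form
does flag it, and the two forms agree to ~0.1% at cohort sizes of 10⁴.
Flagged scans are reported, never removed automatically.

## Centerline geometry

The ON centerline between the nerve-tip and optic-canal-start landmarks is
extracted in stages:

1. **Ridge path.** Landmarks snap to the nearest mask voxels (tolerance
   5 mm; the mask must be one 26-connected component containing both).
   Dijkstra over the voxel graph with edge cost `length/(dt+ε)²`
   (ε = 0.1 mm), dt the Euclidean distance transform, keeps the path on
   the medial ridge — a mesh-free surrogate for Voronoi-based centerlines
   that agrees with them on tubular structures.
2. **Smoothing.** A 5 mm moving average, then a cubic smoothing spline
   with the *largest* smoothing whose RMS residual stays below half a
   voxel, resampled at a fixed 1 mm arc-length step. The averaging
   attenuates a genuine bend of radius R by only ~w²/(24R²) (<0.5% for
   R ≥ 15 mm) while suppressing the lattice-phase wander of the ridge.
3. **Sub-voxel re-centring.** Each sample moves to the centroid of the
   anti-aliased mask's perpendicular slice through it (two passes). The
   slice centroid recovers the tube axis to well under a tenth of a voxel
   and is exact for circular arcs, whose perpendicular sections are
   meridian discs. End samples, whose slices are cut by the tube ends,
   are placed on the refined line instead; the path is then extended
   axially (never laterally) to the landmark arc-length positions, and a
   final gentle spline (RMS ≤ 0.1 voxel) restores C² smoothness.

Without stage 3 the lattice quantisation of the ridge leaves a
~0.5 mm-amplitude bow that reads as ~0.006 mm⁻¹ of spurious curvature on
a perfectly straight nerve; with it the spurious curvature is an order of
magnitude smaller.

Curvature and torsion come from central differences on the arc-length
parameterisation: κ = |r′×r″|/|r′|³ (averaged unsigned), τ =
(r′×r″)·r‴/|r′×r″|² (averaged signed, so a planar nerve averages to 0).
Summaries trim two samples at each end, where one-sided differences are
unreliable. τ is set to 0 where κ < 0.01 mm⁻¹: with κ² in the
denominator, torsion is ill-conditioned on locally straight segments, and
at 0.5 mm voxels its recovery error can reach ~0.06 mm⁻¹ near that
threshold — consistent with torsion being empirically the least reliable
nerve metric in scan–rescan studies. Tortuosity is arc/chord − 1 (0 for
a straight nerve; normative values are then ~0.03–0.04 rather than
~1.03), with an absolute resolution floor of ~0.005 from half-voxel
path-length quantisation over a ~25 mm nerve.

The per-sample radius stored on the centerline is the interpolated
distance-transform (inscribed-sphere) value; its lattice error is about
half a voxel (±5–9% on a 1.5 mm nerve at 0.5 mm voxels). The *reported*
ON radius metric therefore uses the perpendicular cross-section
equivalent radius sqrt(A/π) averaged every 2 mm along the interior, which
is sub-voxel accurate.

## Cross-section areas

An oblique cross-section is measured by anti-aliasing the binary mask
with a half-voxel Gaussian, interpolating it trilinearly onto a
plane-aligned 0.1 mm grid centred at the seed, thresholding at 0.5 and
counting the connected component containing the seed. Without the
anti-aliasing the raw 0.5-level set bulges by up to half a voxel at
unlucky lattice phases (worst-case single-slice error ~5.5% at 0.5 mm
voxels); with it the worst case drops below ~4% at the cost of a
fraction-of-a-percent inward bias on convex sections.

The ONS 3 mm area uses the outer sheath boundary (nerve included, as in
sheath-diameter conventions) on the plane perpendicular to the centerline
3 mm behind the nerve's entry point at the globe — the first centerline
sample outside the globe label, walking from the tip. The "optimal"
variant minimises the area over plane normals tilted up to 30° from the
tangent while pivoting about the same 3 mm point (5° coarse grid, local
refinement to 0.5°); because zero tilt is in the search set it can never
exceed the perpendicular area beyond grid tolerance. The orbital rim
plane is the total-least-squares plane of the four rim landmarks
(smallest singular vector of the centred points), with the normal signed
so the nerve tip is on the positive side — hence rim distances are
posterior-positive (globe centre positive, lens typically negative).

## Deformation map

The scleral surface is the 0.5 iso-surface (marching cubes, run in voxel
space and mapped through the affine) of the globe mask with the lens
counted as interior. Each vertex becomes (r, θ, φ) in the globe-centred
frame — zenith toward the nerve tip, azimuth reference the world +x axis
orthogonalised against the zenith (+y fallback when nearly parallel).
Anterior points (θ > 90°) are discarded — about half the vertices of a
full sphere. The map is the mean radius on a 30 × 72 grid of θ/90° ∈
[0, 1] × φ ∈ [0, 360°), bins uniform in θ (matching the direct θ/90°
normalisation) rather than cos θ; empty bins are NaN. The binned grid,
not a scatter contour, is the canonical data product so maps are
comparable across subjects; φ is measured counter-clockwise viewed along
−zenith and maps are emitted unmirrored for either eye, with the frame
recorded in the sidecar metadata. Aggregation across subjects is the
per-bin mean and sample variance (ddof = 1), with bins missing in any
subject flagged.

The phantom's flattening rule is `r(θ) = R(1 − (1−f)cos²θ)` on the
posterior hemisphere (r = fR at the pole, R at the equator), which gives
a closed-form map truth and the closed-form volume
`V = (2πR³/3)(2 − e + 3e²/5 − e³/7)`, e = 1 − f.

## ICC

ICC(2,1) (two-way random effects, absolute agreement, single measures)
from the ANOVA decomposition of the n-subject × k-session matrix:
`(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))`. Absolute agreement
charges systematic session offsets against reliability, unlike the
consistency form, which is exposed for comparison. The p-value uses
F = MSR/MSE on (n−1, (n−1)(k−1)) degrees of freedom. The implementation
is written out from the mean squares and cross-checked in the tests
against pingouin's ICC(A,1) to 1e-10. Rows with any missing cell are
dropped listwise (single-measure agreement ICC has no canonical
missing-data handling); a zero-variance matrix has an undefined ICC,
reported NaN. Report rows are banded (≥0.9 excellent, ≥0.75 good, ≥0.5
moderate, else poor).

## The phantom: what it emulates, and what it does not

Defaults are sized to normative adult anatomy, chosen once: globe radius
11.3 mm (6.04 cm³ sphere), lens semiaxes 4.5 × 4.0 × 4.5 mm tangent to
the anterior globe interior (lens centre 7.3 mm from the globe centre),
ON radius 1.5 mm and ONS radius 3.2 mm (3 mm-plane area ~32 mm²), nerve
length 25 mm running posteromedially (15° medial, 6° superior) toward the
orbital apex, eyes mirrored at ±20 mm from the mid-sagittal plane, rim
plane 6.2 mm anterior to the globe centre (signed distances +6.2 globe /
−1.1 lens), retroorbital widths 21.4 / 31.2 mm, canal axes 4.56 × 4.09 mm
(area 14.65 mm²), tissue means globe 200 / lens 230 / nerve 150 / sheath
180 / orbit 120 over air 0, noise σ = 10. The oblique nerve is also a
numerical necessity: a lattice-aligned tube repeats the same 2D disc
quantisation error in every slice (−3%/+6% in areas and volumes), an
artifact of rasterisation rather than of the measurement.

The lens is carved out of the globe label (exclusive labels), so the
labelled globe volume truth is the (flattened) sphere minus the lens
ellipsoid; the deformation map re-unions the lens so the anterior surface
is sclera. Rasterisation is an analytic inside-test at voxel centres;
labels, landmarks and truth are noise-free and only the intensity image
depends on the seed, byte-reproducibly. The generator refuses
configurations whose left and right sheath tubes would collide at the
midline.

The phantom deliberately omits: Rician noise statistics (the QC formulas
consume only means and an air-mask σ, for which Gaussian noise is
sufficient), bias fields, ghosting and motion artefacts, extraocular
muscles, bone, partial-volume intensity mixing, and any segmentation
error. Passing the validation therefore establishes that the *measurement
chain* is correct and voxel-quantisation-robust given correct
segmentations; it says nothing about segmentation or registration
quality on real MRI, which upstream tooling must ensure.

## Validation problem sizes and tolerances

The recovery battery measures 20 phantoms (12 in the acceptance script)
at 0.5 mm voxels with randomised radii, lengths, curvatures
(0–0.02 mm⁻¹) and obliquities, drawn within anatomically compatible
ranges. Landmark-derived metrics must be exact to 1e-6 mm; raster-derived
metrics must recover truth within 5%, with absolute floors where the
truth is zero or the magnitude is far below 1: 0.005 for curvature and
tortuosity (half-voxel path quantisation) and 0.1 mm⁻¹ for torsion
(conditioning, as above). Geometry oracles: helix κ = a/(a²+b²) and
τ = b/(a²+b²) within 2% on analytic samples; rasterised quarter-arc
κ = 1/R within 10%. Deformation: a spherical phantom's occupied bins
spread less than one voxel; f = 0.9 flattening at R = 12 reads
10.8 ± 0.3 mm centrally with the rim unchanged. QC: EFC endpoints exact;
SNR/CNR within 5%; the 2 SD rule flags ~4.55% of 10⁴ standard-normal
draws. ICC: variance-ratio recovery at n = 200 within Monte-Carlo error.
All suite randomness is fixed-seeded; the acceptance script derives every
stream from its `--seed`.
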