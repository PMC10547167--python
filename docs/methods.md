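# Methods

## Data model

A segmentation is a stack of binary slices with square in-plane pixels of
side *s* (mm) and slice spacing ΔX (mm). Voxel centers sit at
((col+0.5)s, (row+0.5)s, (i+0.5)ΔX); all estimators work in these physical
coordinates. In-plane connectivity for 2D regions is 8-connectivity
(diagonal pixels belong to one bleed region); the 3D surface shell uses
6-connectivity (face adjacency). These are the standard morphology
conventions; nothing downstream is sensitive to the choice except the exact
border-voxel count entering the roundness index, where 6-connectivity gives
the thinnest well-defined shell. Non-square in-plane pixels are rejected
rather than averaged because a single *s* enters every formula.

## Volume estimators

**Planimetry** is exact with respect to the discrete mask: set-voxel count ×
s²ΔX. Its only error against a continuous solid is voxelization, first-order
in the spacing.

**Truncated pyramid.** Regions on adjacent slices are paired by footprint
overlap in (row, col). When a region faces k counterparts, the overlap graph
component is merged and a single frustum is computed between the summed
areas — k separate frusta would double-count the shared column. A region
face with no counterpart (including before the first and after the last
slice) meets a zero-area virtual slice, contributing ⅓·A·ΔX; the frustum
formula degenerates continuously to this cone-like cap.

**ABC/2 via PCA.** The eigenvectors of the covariance of the set-voxel
coordinates give the principal directions; the axis length along a
direction u is the extent (max − min) of the projections *plus the support
of one voxel along u* (s|uₓ| + s|u_y| + ΔX|u_z|), so a single-voxel slice
measures s rather than 0 and flat regions keep a one-voxel thickness. The
literal "range of x′ where y′ and z′ are zero" definition is unusable on a
lattice — almost no voxel center lies exactly on an axis — so the extent of
all projections is used. Eigenvector signs are fixed (largest-magnitude
component positive) for determinism. The 2D variant analyzes each slice
separately, returns the slice maximizing A, and sets C = (number of occupied
slices)·ΔX; the 3D variant uses the full voxel cloud. ABC/2 itself is the
clinical simplification (4/3)π(A/2)(B/2)(C/2) with π ≈ 3, i.e. A·B·C/2 —
implemented literally, so on a perfectly recovered ellipsoid the estimate
converges to 3/π ≈ 0.955 of the true volume, not to it.

## Roundness index

R = 1 − [10/(n·(abc)^⅓)]·ΣΔ_k over the n border voxels, where Δ_k is the
absolute difference between the voxel's distance to the centroid and the
reference ellipsoid's central-projection radius in that direction. The
weight 10 is a convention kept as the default (exposed as a parameter); R is
dimensionless, scale-invariant, ≤ 1, and deliberately unclamped below 0.

The reference ellipsoid takes its orientation and axis *ratios* from the 3D
principal axes. Its overall scale is set by the median ratio of border-voxel
radius to reference radius, not by the raw PCA extents: border-voxel centers
necessarily lie up to one voxel *inside* the solid's surface, so an
extent-derived ellipsoid overshoots the border shell by ~half a voxel
everywhere and would charge even a perfect digital sphere a systematic
deviation (measured: R ≈ 0.70 at diameter 60 voxels, where the shape is
plainly round). Anchoring the scale on the border shell removes this
discretization bias (same sphere: R ≈ 0.93) while leaving genuine
irregularity fully penalized; a median is used so that a minority of
outlier voxels (knobs, spurs) cannot drag the reference toward themselves.

## Phantoms

Six solids emulate the topological variety of the physical test set:
ellipsoid; convex lens (intersection of two equal balls — the epidural-
hematoma profile); rough shape (ellipsoid radial function modulated by a
seeded band-limited wave field, ±15%); pair/triple pants (a trunk capsule
splitting into 2/3 leg capsules; lower slices show 2/3 separate 2D
components, upper slices one); knobby ellipsoid (ellipsoid radial function
with 24 seeded Gaussian surface knobs of relative amplitude 0.8 — pronounced
protrusions, realized as a star-convex radial field rather than a union with
off-center balls, which is topologically equivalent and admits exact
quadrature); and a random hematoma-like shape with tunable roughness for
cohort simulations. The exact geometry of the physical phantoms is
unpublished; shapes are reconstructed from their names and topology, and
only qualitative behavior (method-error ordering, roundness ranking) is
asserted about them, never their measured volumes.

Voxel membership is by center-point inclusion — the same convention as a
binary radiologist mask — so planimetry is exact for the discrete shape.
Grids use even dimensions so voxel centers straddle the shape center
symmetrically. Default benchmark discretization: ΔX = 1.5 mm (a standard
head-CT slice), s = 0.45 mm (typical in-plane pixel; a free parameter).
All randomness flows through one seeded generator in the spec.

**Reference volumes** are analytic where a closed form exists (ellipsoid;
lens via the two-cap formula), by angular quadrature V = (4π/3)·mean(r(u)³)
on a 400k-point Fibonacci sphere for star-convex solids (cross-checked
against a 100k evaluation to 0.2%), and by fine-grid counting for the
branched pants (isotropic 1.5 mm/refinement spacing, refinement ≥ 8, with a
1.5× finer grid agreeing within 0.2%). **Calibration** to a target volume is
closed-form: uniform scaling of all length parameters scales volume exactly
by λ³, so λ = (target/V₀)^⅓.

The HU simulator fills the mask with uniform values in the water window
(HU 5–8) on a disjoint background, so thresholding at the same window
recovers the mask exactly. It models no CT physics (no noise outside the
window, no partial volume, no beam hardening).

## Statistics

Differences are always planimetry − comparator, so overestimating methods
show negative Bland–Altman bias. The SD of differences uses n−1. The
Wilcoxon signed-rank test drops zero differences, average-ranks ties, and is
exact for n ≤ 15 by enumerating all 2ⁿ sign assignments (variance for the
normal branch is Σrᵢ²/4, which equals n(n+1)(2n+1)/24 minus the usual tie
correction, plus a 0.5 continuity correction). Spearman and OLS are the
standard scipy routines behind the module's contract-checked surface.
Surgical thresholds are inclusive (≥ 30 cm³ EDH; ≥ 30 frontal/temporal IPH;
≥ 50 other IPH): the clinical wording of the evacuation criteria uses
"greater than or equal". No multiple-testing correction is applied
(per-comparison α = 0.05), matching how such method comparisons are
conventionally reported. Regions below 0.5 cm³ are excluded before any
statistic, and excluded ids are logged.

## What the synthetic benchmark does and does not show

The phantom suite exercises the estimators on known geometry at CT-like
discretization. It reproduces the qualitative structure seen on real
cohorts — planimetry and the truncated-pyramid method agree closely, ABC/2
variants err increasingly as roundness falls — but it does not contain
annotation noise, partial-volume boundaries, touching lesions, or reader
variability, so passing it says nothing about segmentation quality on real
CTs, only about the volume arithmetic downstream of a given mask. The
published per-shape measured volumes of the physical phantoms, and all
patient-cohort numbers, depend on objects and scanners not reproducible in
software and are intentionally not asserted.

## Problem sizes

Tests voxelize phantoms at 0.45–1.5 mm spacing (10⁵–10⁶ voxels), use fine
ellipsoids up to ~8 × 10⁶ voxels for the 3/π limit checks, 5000 replicates
for the Wilcoxon null calibration, and 10⁴ pairs for Bland–Altman coverage
— sizes at which every quantity checked is stable to well under its test
tolerance.
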