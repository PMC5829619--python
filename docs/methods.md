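# Methods

This note documents the models, parameter choices and known limitations of
the `leafmotion` pipeline, stage by stage, and what the synthetic scenes it
is validated on do and do not capture.

## Problem setting and assumptions

The input is a series of single-scan point clouds of one potted rosette
plant, one cloud per acquisition time, all in one metric frame (meters).
The scanner does not move between acquisitions, so the static scene
(pot, floor, stem base) is pre-aligned to within the instrument's
repeatability; only the leaves move. The pipeline assumes:

- leaves are approximately rigid between acquisitions — they translate and
  rotate (petiole articulation) far more than they bend; the surface-match
  residual threshold absorbs the residual deformation;
- leaves of one plant present *dissimilar orientations* and do not touch:
  the segmentation separates surfaces by normal homogeneity and spatial
  contact, and cannot split two co-planar blades pressed together;
- a single viewpoint sees one side of the plant; the canopy is treated as
  approximately mirror-symmetric for volume purposes.

## Outlier removal

Per point, the mean distance to all neighbors within a radius (default
0.008 m — a 1.6 cm neighborhood sphere; a k-nearest mode is also provided)
is computed. Over the cloud these per-point means have mean `d̄` and
standard deviation `σ_d`; points above `L_d = d̄ + p·σ_d`, and points with
no neighbors at all, are removed. Statistics are computed once, globally
(two passes), so removal decisions are order-independent.

The confidence multiplier defaults to `p = 3`. On the synthetic fixtures
`p = 2` costs about 3% of genuine surface points — blade edges populate the
upper tail of the distance distribution — while `p = 3` keeps losses below
1% and still removes every isolated interference return by a wide margin
(an isolated point's mean neighbor distance is either infinite or many σ
above the surface distribution).

## Registration and deviation maps

Alignment is verified by point-to-point ICP (nearest-neighbor
correspondences on a k-d tree, closed-form SVD update, centroid-shift
initialization). In production the epochs are already aligned; the pipeline
applies the ICP estimate only when it is small (< 2°, < 2 cm), reporting it
otherwise, so genuine plant movement is never "registered away". Known
target centroids can be fed to the same routine as two small clouds.

Cloud-to-cloud deviation is two-stage. The chamfer stage is the exact
nearest-neighbor distance (tree-accelerated, equal to brute force). The
quadric stage fits `z = a₀ + a₁x + a₂y + a₃x² + a₄xy + a₅y²` by least
squares to the `k = 12` nearest reference points (twice the coefficient
count) in a local plane-fit frame and measures point-to-surface distance by
Gauss–Newton projection, falling back to the vertical residual when the
iteration stalls and to the chamfer distance when the fit is rank-deficient
(fallbacks are counted on the map). The chamfer distance caps the refined
distance: a quadric extrapolating beyond its sampled patch cannot report
more than the nearest-sample distance. On smooth, densely sampled surfaces
the quadric stage removes the sampling-discretization bias of
nearest-neighbor distances.

## Leaf segmentation

Per-point normals default to the smallest-eigenvector of the k-neighborhood
covariance (`k = 20`) with one pass of sign-aligned neighbor averaging.
Smoothing matters: with millimeter range noise and a neighborhood only a
few point-spacings wide, raw normals carry tens of degrees of noise and the
homogeneity statistics would measure the sensor, not the surface. A local
tangent-plane Delaunay mode (area-weighted facet-normal averaging) is
provided as an alternative.

All normal statistics are **axial**: the mean orientation of a cell is the
leading eigenvector of the orientation tensor Σnᵢnᵢᵀ and spreads/angles use
|n·m|. A normal's sign is a convention, and a blade standing on edge must
not appear to carry two opposite normal populations.

The octree starts from the cloud's cubic bounding box and subdivides a cell
while the mean angular deviation of its normals exceeds `spread_tol`
(default 15°), until cells would fall below `min_voxel = 0.018 m` or
`max_iter = 5` levels are reached. Final cells are decomposed into
spatially connected components (single-linkage at `contact_gap = 0.01 m`)
so one cell cannot glue two leaves stacked closer than the voxel size.
Cells with spread above `2·spread_tol` are removed (leaf edges, stem).
Segments grow from the flattest unassigned cell over face-adjacent cells in
genuine point-set contact (several pairs within `contact_gap` — one noisy
point must not bridge an inter-leaf gap), while the candidate cell's normal
stays within `merge_tol = 20°` of the running segment mean and within
`1.5·merge_tol` of the seed normal (the second anchor stops the mean
drifting across a fold onto the next leaf). Contact-compatible groups are
re-merged (a leaf severed at a removed edge band is one surface), remaining
points within `assign_radius = 0.01 m` of a segment join it, and two shape
gates drop non-leaf segments to noise: a blade is a locally planar 2-D
patch, so segments narrower than `min_width = 8 mm` across their second
principal axis (stem strips) or with thickness-to-width variance ratio
above `max_flatness = 0.3` (tubular stem chunks) are not leaves. Segments
below `min_points = 50` are noise.

The paper-anchored values here are the 1.8 cm minimum voxel and the 5
subdivision iterations. The printed homogeneity tolerance ("6 cm" for a
standard deviation of unit normals) is dimensionally inconsistent for unit
vectors; the angular-spread reading with a 15° default is the only
unit-consistent interpretation and is exposed in the configuration.

## Leaf matching across epochs

Candidate segment pairs within 0.15 m centroid distance are scored by a
rigid least-squares 3D surface match: nearest-neighbor correspondences,
residuals projected on local reference-surface normals, 6-parameter
Gauss–Markov update per iteration, initialized from the best of several
coarse PCA-frame alignments (a leaf rotated by tens of degrees is outside
the basin of a centroid-only start). A pair is accepted when its RMS
surface residual is below `lsm_threshold = 0.038 m` (paper-anchored);
divergence surfaces as a non-finite or large residual. Accepted pairs are
assigned one-to-one by centroid proximity with the residual as tie-breaker:
the residual gate rejects implausible surfaces, but leaves of one plant are
similar enough in shape that the residual alone cannot rank pairings, while
leaf displacement between epochs stays well below the inter-leaf spacing.

## Orientation change

A leaf's orientation is its PCA normal: the eigenvector with smallest
eigenvalue of Σ = (X−X̄)ᵀ(X−X̄)/k over the segment's points. Along a track,
signs are chained in temporal order (each epoch's normal is flipped to the
hemisphere of the previous one); a leaf tilting past the horizontal must
not appear to jump hemispheres. This chaining is reliable while the normal
rotates less than 90° per interval — beyond that the axial sign is
genuinely ambiguous, and the generator warns when asked to produce such a
motion.

Movement is the **difference of normals**, taken in temporal order, and is
reported as the spherical azimuth θ = atan2(y, x) and elevation
Φ = arctan(z/√(x²+y²)) of the difference vector, in degrees. atan2 keeps
the full (−180°, 180°] azimuth range that a plain arctan(y/x) would
collapse. Both the per-consecutive-interval series and the cumulative
series against the first epoch are emitted, clearly labeled, since either
is a legitimate trajectory convention. Note the conditioning: when the
normal barely moves, the *direction* of the difference vector is noisy even
though the motion is accurately measured as small; angle tolerances in the
validation therefore apply to prescribed motions of 20° and more.

## Canopy volume

The convex hull of the (optionally symmetry-completed) canopy points,
converted to dm³, summarizes the enveloped space; signed consecutive
differences track opening (positive) and closing (negative). The mesh
builder (boundary triangles of the 3-D Delaunay tetrahedralization, long-
edge filter at 4× the median edge, three λ = 0.5 Laplacian passes) exists
for inspection and area estimates; it is a deliberately simple repair pass,
not guaranteed watertight (the mesh reports its watertightness), and the
volume figures never depend on it.

Symmetry completion estimates the (axial) viewing direction, when not
supplied, by self-occlusion minimization: the cloud is re-projected
quasi-orthographically along candidate azimuths with angular bins matched
to ~3× the point spacing, and the direction hiding the fewest points wins
(covariance-shape estimators fail here — half a rosette is still nearly
isotropic in plan view, but its visibility structure remembers the scan
direction). The mirror plane is then placed at the occlusion rim for
solid one-sided shells (depth ≲ 0.75× width along the view) and at the
median depth for porous canopies, which still span their full depth — back
surfaces show through gaps, only their density drops, so mirroring must
densify rather than extrude a second copy. Mirrored points are tagged
`synthetic = 1`.

**Limitation:** on porous canopies the no-hint view-axis estimate is good
to roughly 10° (solid surfaces: ~1°). In a real acquisition the scanner
position is metadata; passing it as `axis_hint` makes the plane exact.

## The synthetic scenes

`make_plant` builds a rosette of (default) 9 leaves in a 0.31 m canopy on a
0.45 m plant over an 850 cm³ pot — the study's plant-1 scale — with
isotropic Gaussian range noise of 2 mm and 0.5% uniform interference
outliers. Default surface sampling is 1.0 mm, which lands a scan in the
80–100k point range of real single-scan data at this scale. Leaves are
paraboloid-bent ellipses in two interleaved whorls (outer: long, low,
nearly flat; inner: short, higher, steeper), each placed with at least
15 mm clearance from every other blade and the stem/pot — real leaves push
past each other, they do not interpenetrate, and a generator that crossed
blade surfaces through each other would make point-wise ground truth
meaningless. Motions between epochs rotate each leaf rigidly about its
attachment; `draw_motions` keeps moved blades clearance-free too and caps
the per-interval normal rotation at 75°. The generator records per-point
labels, per-leaf analytic mean normals per epoch, and the exact rigid
motions; identical seed and parameters reproduce a scene bit for bit.

What the scenes do **not** emulate: leaf bending between epochs (rigidity
is exact by design, so orientation recovery is an exact round trip —
deformation is a stress-test option, not the default), radiometric effects
(intensity, beam footprint), range-correlated noise, petioles, and real
*Calathea* blade texture. Passing tests therefore demonstrate the
geometry-processing chain under the stated study conditions, not robustness
to deformation or to scanner-specific artifacts.

Tests run the generator at 4 mm sampling (segmentation, tracking,
pipeline), 2.5 mm (orientation recovery) and 4.5 mm (ICP recovery); the
acceptance script uses 2.5 mm. These sizes keep the whole suite at a few
minutes while leaving every segment hundreds of points strong.

## Numerical conventions

- Internal unit is meters everywhere; volumes are converted once, to dm³.
- ASCII formats write 17 significant digits, so I/O round-trips IEEE
  doubles bit-exactly.
- Seed-cell selection ties break by lowest spread, then most points, then
  lowest cell index; segments are numbered by size. All randomness flows
  from explicit seeds; pipeline reports are bit-identical for identical
  configuration and inputs (wall-clock time is logged, never reported).
- Degenerate inputs: clouds under 2 points pass filtering unchanged with a
  warning; collinear segments raise on normal estimation; coplanar point
  sets raise on hull volume; a cloud with no horizontal spread requires an
  explicit symmetry-axis hint.
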