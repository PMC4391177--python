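# Methods

## Coordinate conventions

All coordinates are millimetres. The MRI patient coordinate system is the
reference frame: registration maps catheter (EMM) space into MRI space, and
all downstream processing (exclusion, projection, densities) happens there.
Meshes are triangulated surfaces with 0-based indices; the endocardial mesh
is open at the base (a single boundary loop, the basal rim) and closed at
the apex.

## Point-to-surface distance

The registration error metric and the ICP correspondence both use the exact
shortest Euclidean distance from a point to the triangulated surface. The
implementation classifies the closest point per triangle (vertex, edge or
interior region) and minimises over candidate triangles selected by a
KD-tree over triangle centroids. The candidate radius is the distance to
the nearest centroid plus the largest centroid-to-corner distance in the
mesh, which provably contains the minimising triangle, so the accelerated
result equals the exhaustive per-triangle minimum to machine precision
(asserted against two independent oracles in the tests). Ties are broken by
the lowest face index for reproducibility. Degenerate triangles
(area < 1e-9 mm²) are dropped at construction with a logged warning.

## "Inside the mesh" test

Whether a catheter point lies inside the imaged ventricle is decided
against the volume enclosed by the endocardial mesh after capping the basal
rim with a triangle fan on the rim's least-squares plane. The test itself
is the generalised winding number (sum of signed solid angles), which is
robust for any point at least ~1e-6 mm off the surface and needs no ray
tie-breaking; the capped mesh is made consistently oriented first. Meshes
with more than one boundary loop are rejected rather than guessed at.

## Registration

**Landmark phase.** Weighted absolute orientation in closed form: with
weights wᵢ, the rotation is the SVD polar factor of the weighted
cross-covariance of the centred landmark sets (determinant-corrected to be
proper), and the translation follows from the weighted centroids. Defaults:
apex weight 10, each coronary ostium 1. At least three non-collinear
correspondences are required; collinear sets raise a degenerate-
configuration error (the second singular value vanishes).

**ICP phase.** Correspondence is point-to-surface (the footpoint), matching
the error metric, not point-to-vertex. Each iteration solves the uniform-
weight closed-form fit of the current point positions to their footpoints
and composes it onto the running transform. The cumulative rotation
relative to the initial transform is then decomposed into intrinsic angles
about three anatomical axes and each angle is saturated at its limit
(sagittal 10°, transverse 20°, coronal 20° by default); the translation is
re-fit for the clamped rotation. The anatomical frame defaults to: long
axis of the mesh (transverse-plane normal is irrelevant here — the
transverse *rotation* axis is the long axis), the in-plane direction toward
the right coronary ostium (sagittal rotation axis, i.e. the left–right
axis), and their cross product; it can be overridden.

Convergence: stop when the mean-error improvement falls below 1e-4 mm, the
transform update falls below 1e-6, or 100 iterations elapse. A candidate
iterate that would *increase* the mean error is rejected and iteration
stops, which makes the mean error non-increasing by construction — point-
to-surface ICP with clamping does not otherwise guarantee descent.

**Exclusion.** A point is excluded when its distance to the surface exceeds
the margin (default 5 mm) and it is either outside the capped volume or its
footpoint lies on the basal rim (the catheter beyond the imaged anatomy,
e.g. the outflow tract). Exclusion removes points from error calculation
and all further processing but never reorders the dataset.

**Manual phase.** `manual_adjust` composes interactive corrections
(intrinsic rotations about the anatomical axes in the fixed order sagittal,
transverse, coronal, then a translation) onto a transform as a pure
function; the pipeline itself never invokes it.

## Transmurality

The wall is interrogated per endocardial vertex with a chord construction:
in the vertex's short-axis slice plane, a ray from the endocardial
centroid through the vertex crosses the endocardial and epicardial
contours; transmurality is the scar length along that wall chord divided by
the wall length, clamped to [0, 1]. Vertices between slice planes blend the
two adjacent slices linearly in z; the mesh may overhang the contour stack
by at most one slice spacing. Rays that fail to cross both contours (in
practice only the apex vertex, where the ray direction is undefined)
inherit the nearest valid vertex's value with a logged warning. The chord
construction is the standard wall-thickness interrogation for LGE
transmurality and is analytically verifiable on annulus phantoms; exact
agreement with a segment-area-based estimator is not expected and the
phantom tests bound the vertex-level error instead (MAE ≤ 0.05 at the
default mesh resolution).

Classification uses half-open bins: exactly 0 is its own class (viable
wall), then (0, 0.25], (0.25, 0.5], (0.5, 0.75], (0.75, 1]. Triangle class
is the majority vote of its three vertex labels with ties resolved to the
lower class; class areas therefore sum exactly to the total mesh area.

The border zone is the marching-triangles isocontour of the vertex field at
the chosen threshold (default 0.5): edge crossings by linear interpolation,
chained into polylines, open chains traced before closed loops. A scar
region that touches the basal rim yields an open chain ending on the rim; a
contained scar yields a closed loop.

## Projection of catheter scalars

Each point's scalar is attached at its surface footpoint. A vertex within
the support radius (default 15 mm) of at least one footpoint receives a
distance-weighted local linear fit (moving least squares with 1/d²
weights) evaluated at the vertex; vertices with no footpoint in range stay
masked — measurements are never extrapolated into unmapped regions. The
local fit reproduces constant and linear fields exactly wherever the
neighbourhood spans a plane (three non-collinear footpoints suffice: the
minimum-norm solution carries no gradient normal to their plane), which a
convex inverse-distance average cannot do near coverage boundaries (its
positional bias is ~R/π there). Degenerate neighbourhoods (fewer than three
points, or rank-deficient) fall back to the weighted mean. The estimate is
clamped to the overall input-value range, so projected values never
overshoot the measurements.

## Bullseye parameterisation

Radius is the vertex height above the apex along the long axis, normalised
by the mean rim height (apex 0, basal rim 1) — a monotone, landmark-anchored
parameter; meridian arc length would differ only by a smooth radial
reparameterisation. Angle is the circumferential position about the long
axis measured from a fixed reference direction, by default toward the right
coronary ostium, so maps are comparable across datasets; the reference is
recorded in the PNG's JSON sidecar. The raster is filled triangle by
triangle with barycentric interpolation in disc coordinates; triangles
straddling the angular seam are unwrapped first. Colour scale: transmurality
is fixed to [0, 1]; voltages are auto-scaled with the limits recorded in the
sidecar (published voltage cut-offs vary too much to hard-code).

## Densities and ANOVA

Each non-excluded point is assigned the class of its footpoint's triangle;
density is count/area per class. A class with zero area but points is
reported with infinite density. Across several maps, a one-way ANOVA
compares densities between classes, using only classes with at least two
maps contributing (a class absent from a map contributes no observation).
Note a statistical subtlety established during development: with a *fixed*
number of points per map the class counts are multinomially constrained
(negatively correlated), which inflates the F-test's actual size to
~11–16 % at nominal 5 %; with map sizes that vary (as real acquisitions
do), the test is conservative. The simulation tests therefore use maps of
different sizes.

## Synthetic phantom

The phantom emulates a porcine left ventricle: truncated-ellipsoid
endocardium (semi-axes 25 × 25 × 45 mm) and epicardium (+10 mm wall), open
at the base (80 % of the long axis kept, single boundary loop, ~102 cm²
endocardial area), short-axis contours every 5 mm, and a wedge scar
prescribed by angular sector, wall-depth fraction and apicobasal range
(default 90° sector, depth 0.6, full length). EMM sampling is area-uniform
on the endocardium (triangle-area-weighted selection, uniform barycentric
draw) with isotropic Gaussian position noise (default σ = 1 mm, standing in
for catheter and respiratory jitter), carried into the catheter frame by
the inverse of the prescribed true transform; the three landmarks are
noise-free by default. Sixty-six points per map mirrors a typical
acquisition. Voltages and shortening follow a linear healthy→scar ramp in
true transmurality (unipolar 12→4 mV, bipolar 3→0.8 mV, LLS 12→2 %) plus
0.5 mV noise; an uncoupled mode draws them independently of scar to emulate
the poor EMM/LGE agreement seen in vivo. One seeded RNG stream drives each
dataset, so generation is bitwise reproducible.

What the phantom does **not** model: real endocardial trabeculation and
shape variability, respiratory-correlated (non-isotropic, non-white) motion,
catheter contact-dependent voltage artefacts, segmentation error in the
contours, and LGE partial-volume effects. Passing the phantom tests
therefore demonstrates correctness of the algorithms under known ground
truth — not clinical-level registration error, which in vivo is dominated
by exactly the unmodelled effects.

## Problem sizes and tolerances

Default phantom meshes use 24 rings × 48 circumferential vertices
(2 256 triangles); statistical tests use 10 × 20. Registration recovery is
assessed over 20 seeds (median rotation/translation error), distance
exactness on 200 random points per mesh at 1e-9 mm, the landmark solver on
100 random transforms at 1e-9, and transmurality recovery at vertex MAE
≤ 0.05. Geometric tolerances: degenerate-triangle threshold 1e-9 mm²,
barycentric validity 1e-9, ICP convergence 1e-4 mm.

## Known limitations

- The inside/outside test requires exactly one boundary loop; meshes with
  holes must be repaired upstream.
- The chord transmurality assumes roughly star-shaped contours about their
  centroid; strongly concave endocardial contours could be crossed more
  than once (the first crossing is used).
- The contour stack must share the mesh's z axis; oblique slice stacks must
  be resampled upstream.
- Bullseye rasterisation is per-triangle and can leave sub-pixel gaps at
  very coarse resolutions; the default (200 px) shows none on the phantom.
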