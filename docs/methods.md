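# Methods

## The simulated microscope

The optical train of a common-main-objective (CMO) surgical microscope is
reduced to its geometric essentials: all lenses are ideal, beam paths
behind the main objective are parallel, magnification is 1, and depth of
field is unlimited.  Under these assumptions the observation channels can
be replaced by ideal pinhole cameras placed on the principal plane of the
main objective.  Cameras sit equidistantly on a ring whose diameter `d`
equals the maximum usable stereo baseline (default 30 mm) at working
distance `h` (default 400 mm) above a common reference point `F`, and all
look at `F`.  Every aperture is then `sqrt(h² + (d/2)²) ≈ 400.28 mm` from
`F` — the focal length of the simulated main objective — so an object at
`F` appears with identical magnification in all cameras.

Camera pose uses the look-at parametrization: `l = (a − F)/|a − F|` (from
the reference point toward the aperture; the camera views along `−l`),
`r = up × l`, `u = l × r` with world up-hint `(0, 1, 0)`.  The extrinsic
matrix stacks rows `(r, u, −l)` with translation `−R·a`; note this matrix
is orthogonal but improper (det −1) — the negated third row flips the
depth axis so scene points get positive depth.  The intrinsic matrix is
`diag(−f/sx, −f/sy, 1)` with zero skew and zero principal-point offset;
`f = sx = sy = 1` by default since sensor resolution cannot affect a
continuous-space area computation.  Only the FOV matters: a rectangle
(default 36 × 24 mm, a surgical microscope's field at 8× magnification)
defined in the focal plane — the plane through `F` normal to the viewing
axis — and converted to image-space half-extents by similar triangles.
Illumination is assumed homogeneous and gapless; visibility is purely
geometric.

## Exact visibility and the reconstructable subset

For each camera, in order:

1. **Culling.** A face survives iff the dot product of its outward normal
   with the viewing direction is strictly negative (zero = contour face,
   invisible by definition) and its image is not entirely outside the FOV
   rectangle.  Faces whose image crosses the FOV border are flagged.
2. **Occluder detection.** Image-space broad phase by enclosing circles
   (circumcenter where well-conditioned, centroid fallback; radius always
   the max center-to-vertex distance, so the circle provably contains the
   triangle), then positive-area overlap of the image triangles.  For a
   confirmed pair, the face with the greater *minimal depth* — the
   smallest Euclidean distance from the aperture to any of its vertices —
   is the occludee.  Exact min-depth ties (shared nearest vertices,
   silhouette folds) are ordered by mean vertex depth; double ties are
   skipped with a warning.
3. **Clipping.** Flagged faces are intersected with the FOV rectangle;
   then the union of all known occluder images is subtracted.  The result
   is back-projected onto the face's plane (aperture-ray × plane
   intersection) and stored in the face's local 2D frame, an isometry in
   which polygon area equals true 3D area.

A face's reconstructable region is the set of its points seen by at least
`T` cameras (`T = 2` throughout the experiments).  Two strategies compute
it and are tested to agree: literal enumeration of all T-subsets of the
seeing cameras (with a combinatorial cap, default 10⁶), and a
divide-and-conquer coverage merge (`lev_k = a_k ∪ b_k ∪ ⋃ (a_i ∩ b_{k−i})`),
which needs O(M log M) polygon overlays instead of the O(M²) a sequential
fold costs on dense rings.  Faces fully visible to ≥ T cameras shortcut
both.  Areas are summed per face and per region tag; normalized tables
divide by the 360-camera benchmark (cameras every 1°, ≈0.26 mm apart —
adjacent images overlap almost completely, so this is the most complete
reconstruction the ring permits).

### Known approximations

* The orientation (backface) test uses the camera's global viewing axis,
  not per-point view rays — faithful to the simulated algorithm, and an
  error only within ~4° of silhouettes at this working distance.
* The minimal-depth ordering is a heuristic: a large face at a grazing
  angle can out-rank an occluder that is nearer along the overlapping
  rays.  Mesh resolution bounds the error (see generator defaults); the
  residual bias measured against ray casting on the artery fixture is
  ~0.1 % of total area.

## Synthetic surgical sites

The generator emulates deep operative corridors: a 60 × 60 mm block with a
channel of circular (25 mm diameter) or superelliptical
(`|x/a|^p + |y/b|^p = 1`, axes 42.5 × 22.5 mm, p = 2.5) cross-section,
depth 50 or 100 mm.  Regions are tagged `anatomy` (channel floor and
inserted structures), `wall`, `top_surface`, `exterior`; tags are inherited
by clipped fragments, so area accounting per region survives the pipeline.
Anatomy options:

* `flat_relief` — a seeded sum of four random-wavevector sinusoids
  (amplitude 2 mm) scaled by a radial falloff vanishing at the wall;
* `spanning_artery` — a capped tube (8 mm diameter) across the channel,
  centerline 30 mm above the floor, ends embedded 2.5 mm into the wall so
  the caps are buried in solid material;
* `overhang` — a bulge protruding from the wall into the corridor, placed
  slightly off the y = 0 symmetry plane so no camera sees two exactly
  depth-tied mirror faces.

Meshes are watertight by construction (shared vertex indices throughout;
inserted components are separately closed).  Discretization defaults:
128 boundary segments (wall lateral-area error < 0.1 %), 6 mm wall bands
and 5 floor rings — the band height bounds the minimal-depth
misclassification window where structures cross the wall visually.  The
channel floor sits at z = 0 with a configurable axial offset; the sweep
experiments center the site on the focal point (`z_offset = −depth/2`),
the placement under which the FOV windows widen below the focal plane and
the lower channel wall saturates with few cameras.  What the generator
does **not** emulate: real anatomical texture and topology (vessel
networks, undercuts at many scales), so absolute areas and saturation
levels are not comparable to clinical sites — only the qualitative
behaviour (dominant 2→4 gain, saturation by ~8 cameras, top-surface
dominance of late increments) is.

## Experiments

Sweeps evaluate camera counts (default 2, 4, 6, 8, 16, 32, 64, 128, 256,
360) with equidistant placement, report absolute and normalized areas with
and without the `top_surface` region (excluded from numerator and
denominator; the draped top rim is clinically irrelevant), and increment
columns `Δ` with the percentage convention `Δ / previous value`.
Saturation is described by `‖Ar‖(n) = c₀ − Σ aᵢ·exp(−bᵢ·n)` (n ∈ {2, 3}
phases, aᵢ, bᵢ > 0 via log-parametrization), fitted by multi-start
Levenberg–Marquardt; 3-phase starts include the best 2-phase solution with
a vanishing third phase, so nested-model residuals are monotone.  The fits
are descriptive only.

## Verification

A Monte-Carlo oracle, independent of the clipping code, samples surface
points area-uniformly and decides visibility by batched Möller–Trumbore
segment casting (source face excluded by id, origins offset 1e-6 mm along
the normal, minimum hit parameter 1e-5 of the segment).  Per-point
agreement with the exact pipeline is total on plate and channel fixtures
and within ~0.1 % (one-sided, the min-depth heuristic) on fixtures with
free-floating occluders.  Acceptance-style checks assert agreement within
three binomial standard errors at 20 000 samples.

### Numerical choices

* Tolerances: positions 1e-9 mm, image coordinates 1e-9, sliver cut-off
  `AREA_EPS = 1e-8 mm²`, occlusion depth ties 1e-9 mm.  Image-space area
  thresholds are `AREA_EPS` scaled by the camera's mm→image factor.
* Boundary-touching polygons (zero-area intersection) never count as
  overlapping — adjacent mesh faces are not mutual occluders.
* The coverage merge snaps fragments to a 1e-9 mm grid: the same physical
  edge seen through different cameras differs by ~1e-13 mm, and without a
  common grid those near-coincident arcs defeat robust noding and inflate
  intermediate unions.
* Decay-fit recovery experiments use a dense log-spaced grid (2000
  abscissae in [2, 360]): a Fisher-information calculation (asserted in
  the test suite) shows 1 % noise on a 10-point sweep leaves the rate
  parameters with 13–17 % standard errors, so no fitter could recover
  them to 5 % there; on the dense grid every parameter's 3σ error is
  below 5 %.
* Test and acceptance runs use desk-scale meshes (40 boundary segments,
  4 floor rings, ≤ ~1800 faces) and the sweep counts (2, 4, 6, 8, 16,
  360); the saturation behaviour is unchanged from finer discretizations,
  only absolute areas shift by the chord-shortening factor.

## Limitations

Reconstructability here is a visibility criterion: no feature matching,
reconstruction error, lens aberration, depth of field or lighting effects
are modeled, so all areas are theoretical maxima for ideal optics.  The
per-face depth ordering can misclassify grazing occlusions (bounded by
mesh resolution, see above).  Results depend on the site's area
composition (wall vs. anatomy vs. top surface); the synthetic sites are
wall-dominated, which lowers normalized low-camera values relative to
anatomy-rich sites.
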