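# Methods

## Problem

Soft-tissue landmarks on the face — pronasale (nasal tip), columella, the
upper and lower lip points, and the two cheek prominences — are convex
protrusion points that clinicians digitize on 3D reconstructions of CBCT
scans. Manual clicks on a rendered surface are imprecise; `terracemark`
implements a digitization scheme whose key idea is that at the coarse voxel
sizes typical of craniofacial CBCT (0.3 mm), a *binary* marching-cube
reconstruction produces stepped contour lines and flat "mountain tabletop"
plateaus exactly at locally most-protruded regions. Averaging the plateau
("tabletop") that contains a rough manual click yields a computer-calculated
(CC) landmark that is invariant to where on the plateau the click landed.

## Surface reconstruction

`volume_io` binarizes the scan with a global Otsu threshold computed on a
256-bin histogram of the whole volume. Candidate thresholds are the upper
edges of nonempty bins (cuts inside a run of empty bins partition the data
identically, so only the lowest is considered) and ties break toward the
lower threshold, making the result deterministic for a fixed binning. The
tissue class is the brighter one by default (`invert` flips this); only the
largest 26-connected component is kept. 26-connectivity avoids fragmenting
thin structures such as nostril rims; no hole filling is applied because
internal airways cannot affect the external isosurface.

`marching` contours the binary mask at isovalue 0.5 with a marching-cubes
table generated programmatically, so the corner/edge conventions are
auditable in one module. With binary data, linear edge interpolation
degenerates to edge *midpoints*; this is embraced rather than smoothed away,
because the resulting terraces are the plateaus the landmark algorithm
averages. Two generator details matter:

* **Face rule.** The classic 15-pattern case system (256 configurations
  modulo 24 rotations and inside/outside complementation; both counts are
  verified by brute-force canonicalization and Burnside's lemma) has known
  holes when complementary ambiguous cases are stamped naively. Each table
  entry is therefore built by walking contour segments on the six cell
  faces under a fixed rule — *diagonally opposite inside corners on a face
  are never connected* — which depends only on absolute voxel states, so
  the two cells sharing a face always agree and closed components mesh
  watertight (asserted on every phantom; Euler characteristic 2 on genus-0
  solids). The 2D (marching squares) dictionary uses the analogous
  complement-invariant saddle rule: the main-diagonal corner pair is never
  connected.
* **Fan pivot rule.** Contour polygons are fan-triangulated from a pivot
  chosen so that no fan diagonal joins two midpoints lying on a common cell
  face; otherwise the diagonal can coincide with the neighbouring cell's
  contour segment and create a non-manifold (four-face) edge where voxels
  touch diagonally. A safe pivot exists for every polygon of every
  configuration (checked exhaustively).

Triangles are wound counter-clockwise seen from outside; vertex normals are
area-weighted averages of incident face normals (raw cross-product sums,
which weight by area for free). The optional "block-noise" pass
(`smooth_preserving_plateaus`) only re-estimates normals by repeated 1-ring
averaging and never moves vertices, so the terraced geometry the landmarks
depend on is preserved; surface simplification beyond this is out of scope.

## CC landmarks

Each landmark carries a fixed anatomical protrusion direction (catalogued as
a raw vector with ±0.5 components, e.g. `(0, -0.5, 0)` for the anterior
landmarks or `(0, -0.5, -0.5)` for the columella; only the direction is
meaningful and it is normalized before use). Axis convention: +x =
subject-left, +y = subject-backward, +z = up.

Given a starting point, `find_tabletop` snaps it to the nearest mesh vertex
(ties to the lowest index), rejects back-facing starts (per-vertex mesh
normals are used *only* for this check), and collects the edge-connected
patch containing the start within

* a Euclidean ball of `radius_px = 50` voxels (15 mm at 0.3 mm), and
* a slab `|(v - start) . n| <= band_px = 1` of thickness 2 px centred on the
  start, perpendicular to the landmark's *fixed* normal.

"Pixels" are voxel units throughout — the method operates in image space and
converts to mm only afterwards. Connectivity is what separates two
same-height tabletops (e.g. a bifid lower lip): without it the 50 px ball
would merge them. The CC point is the unweighted mean of the member
vertices; mm coordinates follow the affine reference map
`mm = (voxel - (266.5, 266.5, 266)) * 0.3` with `d = ||mm||`.

`consistency_check` re-digitizes from the CC point displaced by 0.5–4.0 px
in four directions and reports the voxel-space distance between the second
and original CC point for all 32 cells; a move that hops to a different
patch is reported with its nonzero distance, never suppressed. The screen
terms up/down/left/right are realized as ± the unit projections of the
global z- and x-axes onto the landmark's tangent plane, which reduces to ±z
and ±x for anterior-facing landmarks. A single digitization pass is used
(no fixed-point iteration of the tabletop search); it already achieves the
zero-displacement result on plateaus.

## Reliability statistics

`reliability` implements the validation battery for repeated digitizations:
two-item Cronbach's alpha `2 (1 - (s1^2 + s2^2) / s_{1+2}^2)` with unbiased
variances (intra-examiner: session 1 vs 2; inter-examiner: each examiner's
two-session mean as the item), absolute per-axis and distance differences
Δx/Δy/Δz/Δd summarized per landmark as mean and SD across subjects (SD of
the absolute values; the absolute reading is forced by the nonnegative
means such tables report), the classical paired t-test on per-subject
differences, and the minimal sample size for a two-sided paired t-test by
exact noncentral-t power iteration (no normal approximation): at
dz = 0.5, α = 0.05, power = 0.80 it returns n = 34. Degenerate inputs
(constant measurements, zero-variance differences) raise instead of
returning a number.

## Synthetic phantoms

`synthetic` builds the validation data: a stylized head — an ellipsoid
(semi-axes ≈ 16.5 × 15 × 21.6 mm at the 160³ test scale) cut by four planar
lattice "panels": a flat anterior facial plate (⊥ y) carrying pronasale and
the lip points, a z-windowed 45° subnasal notch for the columella, and two
global 45° cheek chamfers — with a flat-topped frustum bump per landmark
(facet halfwidth 8 px, widening half a voxel per lattice step, capped)
whose apex protrudes 5 lattice steps out of its panel. Tissue is 180,
air 5, with Gaussian intensity noise of SD 10 (well inside the Otsu regime:
the class gap is ≈ 9 noise SDs, so the binarized solid equals the analytic
solid with overwhelming probability at this volume size).

Two exact lattice facts make this the regime in which the tabletop
algorithm is *exact*, not merely accurate:

1. Binary marching-cube vertices sit at cut-edge midpoints, so an
   axis-perpendicular lattice cut — and equally a perfect 45° staircase
   cut — meshes into a surface whose vertices are exactly coplanar. Every
   bump facet is therefore a single flat tabletop whose vertices share one
   projection onto the landmark normal, including the 45°-oriented
   columella and cheek facets.
2. With the facet 5 steps in front of its panel, everything that is not the
   bump's facet or first flank ring lies either outside the 1 px band or in
   a band-satisfying region that is edge-disconnected from the facet patch.
   The member set of the tabletop search is then an *absolute* vertex set,
   independent of which facet vertex seeds it — which is what makes CC
   points from different starts identical and the perturbation grid exactly
   zero.

The panel standoff, facet size (≥ 8 px, so the plateau spans well over the
minimum of ~5 vertices) and the ≥ 24 px midline landmark spacing were chosen
once so that neighbouring bumps' in-band structures stay ≥ 2 px apart under
the per-subject jitter (integer in-plane lattice offsets of up to ±2 voxels
plus continuous head-axis jitter; the three midline facets share one
vertical offset so they stay coplanar). The 160³ grid is a desk-scale crop
of the 533³ / 16 cm field of view; `shape=533` reproduces the full
acquisition geometry, while grids below 160 are rejected because facet
sizes and the 1 px band are fixed lattice quantities that cannot shrink with
the grid.

What the phantoms deliberately do *not* model: anatomy beyond convex
protrusions (no concave landmarks such as soft-tissue gonion — the tabletop
construction has no meaning there), CT physics (beam hardening, scatter,
metal artifacts), and surfaces whose protrusion is not locally
panel-plus-bump shaped. Passing the exact-zero tests therefore shows the
algorithm behaves as designed in its intended geometric regime; on real
scans the same guarantee holds only insofar as a landmark's neighbourhood
is terrace-like at the scan resolution.

`generate_rater_series` simulates examiners as truth + per-rater bias +
isotropic Gaussian per-click jitter, seeded; `cohort_cc_series` runs the
full pipeline on a randomized cohort and digitizes every landmark from two
independent starting points (3 px "up" and 2.5 px "right" of the apex),
emulating two examiners.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.default_rng` seeds; phantom
  generation, rater simulation and the CLI pipeline are bit-reproducible
  for a fixed seed.
* Nearest-vertex snapping breaks exact ties toward the lowest vertex index.
* Band and radius tests use `<=`, so boundary vertices are members; all
  boundary quantities on the phantoms are half-integers or multiples of
  1/√2, away from the cutoffs or exactly on them consistently in every
  invocation.
* Degenerate inputs raise (`ValueError`) rather than warn: constant
  histograms, empty masks, empty tabletops, back-facing starts, constant
  measurement vectors, zero-variance paired differences.
* Meshes whose foreground touches the volume boundary are returned open
  with an `open_boundary` flag, not rejected.

## Known limitations

* The marching-cubes extractor is specialized to binary masks (midpoint
  vertices); it does not do general scalar-field interpolation.
* Non-manifold *vertex* contacts (two surface sheets sharing a vertex at
  diagonally touching voxels) remain possible, as in any binary marching
  cubes; only non-manifold edges are prevented.
* `find_tabletop` on strongly concave or saddle-shaped regions returns
  whatever connected in-band patch contains the start; the CC point is only
  anatomically meaningful for convex protrusion landmarks.
* DICOM support covers single-frame image series with consistent
  orientation; anisotropic spacing is accepted but merely flagged.
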