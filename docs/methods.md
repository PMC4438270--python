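# Methods

This note documents the models, geometric constructions, numerical choices
and known limitations of the `coronoid` toolkit. It is the package's own
account of its science; every number quoted here is computed by the test
suite or by `scripts/acceptance.py`.

## Problem setting

The coronoid process of the human mandible is a thin, geometrically
complex flange on the superior edge of the ramus. When its geometry is
missing or damaged (trauma, resection), a patient-specific model must be
predicted from measurements that *are* available — typically a handful of
standard morphometric distances read off radiographs or CT scans. The
toolkit implements a landmark-based parametric ("predictive") model of the
coronoid region: a fixed template of 39 anatomical points whose
coordinates, expressed in a specimen-specific anatomical frame, are each
an affine function of ten morphometric parameters.

The pipeline has four stages, each usable on its own:

1. **Object coordinate system (OCS)** — a specimen-specific frame built
   purely from named landmarks.
2. **Anatomical point extraction** — section curves obtained by
   intersecting coordinate-plane offsets with the surface mesh, sampled
   into the labeled template points.
3. **Parametric regression model** — per-point, per-axis multiple linear
   regression on the parameter vector.
4. **Evaluation** — maximal coordinate errors per specimen and axis,
   leave-one-out cross-validation, and deviation of a lofted surface from
   the reference mesh.

## Object coordinate system

Given landmarks (mm, any rigid frame):

* origin `O` = midpoint of the left and right mental-foramen points
  (`BO_left`, `BO_right`);
* `x` = unit vector from `BO_left` to `BO_right` (the mediosagittal plane
  has this normal and contains `O`);
* the mandibular (base) plane is normal to the mediosagittal plane and
  leveled at the most inferior of a configurable candidate list
  (default `Gn`, then `Go_left`/`Go_right`): `z` is the unit component of
  `O − L` perpendicular to `x`, where `L` is that landmark — i.e. the base
  plane contains `L`, and is translated to `O` for use as a coordinate
  plane;
* `y = z × x` (posterior-pointing), giving a right-handed frame; the
  anteroposterior plane has normal `y` and contains `O`.

The mental-foramen landmarks are used exactly as supplied (no
foramen-boundary averaging — meshes carry no labeled boundary). With a
single inferior landmark the base-plane orientation is necessarily the
perpendicular-drop construction above; when several are supplied, the one
most inferior along the provisional down direction is used. The
construction depends only on landmark positions, so OCS coordinates are
rigid-motion invariant (verified to 1e-6 mm under random rotations and
translations).

Tolerances: geometric predicates 1e-6 mm, linear-algebra identities
(orthonormality, unit norms) 1e-9; both configurable.

## Section curves and point sampling

Plane–mesh intersection uses exact triangle–plane crossing with segments
chained by shared mesh-edge identity (via `trimesh`), producing maximal
ordered polylines; closed loops are flagged. Multiple loops are returned
sorted by descending length, or filtered to the loop nearest an optional
region-of-interest point. Degenerate faces are removed at load; open
meshes simply yield open polylines.

Curves are stored as polylines with chord-length cumulative
parameterization — deterministic and faithful to mesh resolution. For
sampling, a natural (periodic, when closed) cubic spline through the
vertices can be evaluated at arclength fractions; `k/(n−1)` for `n` even
points on an open curve, `k/n` on a closed one. Anchored sampling returns
the exact nearest polyline point to a named landmark (e.g. a template
point pinned to the gnathion). The `curves` CLI command samples with
linear (chordal) interpolation instead of the spline so that every
emitted point lies exactly on the mesh surface; the smoothing spline is
available in the library (`smooth=True`, the default there) when a
visually smooth curve matters more than surface membership.

The default template (`hmcp39`) is 39 points, `P1..P39`, organized as
three section rows of 13 — the row structure is what the surface loft
consumes. Default section levels are 0.25/0.50/0.75 of the
notch-to-condyle height.

## Morphometric parameters

The ten distances (mm), in fixed order d1..d10: Gn-IdD, Go-GoD (bigonial
width), Ko-KoD (bicondylar breadth), VTM (body height), STM (body
breadth), DTM (mandibular length), MSR (minimum ramus breadth), MVR
(maximum ramus height), VKo (condyle height), Gn-KoD. Point-to-point
parameters are Euclidean distances between named landmarks. The three
that require the mesh are operationalized as cross-section extents in the
OCS frame:

* **VTM** — extent along `z` of the body section through the
  mental foramen, cut perpendicular to the in-base-plane body axis
  (`Go − Gn` with its `z` component dropped);
* **STM** — extent of the same section along the horizontal direction
  perpendicular to that axis;
* **MSR** — minimum, over 11 stations at 25–75 % of the `Go→Kon` segment,
  of the section extent along the anteroposterior direction
  (`(Kon−Go) × x`, normalized), sections cut perpendicular to `Go→Kon`.

DTM is the distance from the chin point (a `Pog` landmark when supplied,
else `Gn`) to the line through the two gonia; VKo is the component of
`Kon − MU` perpendicular to the `Go→Kon` axis. Mesh-based values may also
be supplied directly (`overrides`), e.g. from a measurement sheet, which
lifts the mesh requirement. Bilateral parameters use the configured side
(default: right, the modeled side); Go-GoD and Ko-KoD are inherently
bilateral.

## Regression model

For each of the 117 (point, axis) responses, `Y = X B + E` with
`X = [1 | d1 … d10]` (n × 11). The fit minimizes `‖Y − XB‖²` via singular
value decomposition; singular values below `1e-10 ×` the largest are
treated as zero (configurable). When the design is column-rank-deficient —
always the case for n ≤ 11 specimens — the minimum-norm least-squares
solution is returned and the diagnostics carry an explicit rank warning.
Minimum-norm via SVD was chosen because it is deterministic, reproducible,
and standard; a black-box normal-equation solve would return an
unspecified member of the solution set. The diagnostics nevertheless
report the normal-equation quantities (Gram matrix `A = XᵀX`, its
pseudoinverse `K`, fitted values `M = XB`, residuals `E = Y − M`) for
auditability; for full-rank designs `XᵀE = 0` holds to 1e-6.

Coefficient files store full double precision (`%.17g`, re-read with
round-trip parsing, so serialization is bitwise lossless). The published
four-point reference table bundled in `coronoid.reference` is a 3-decimal
snapshot and is only ever compared at that precision. No regularized or
stepwise variants are provided — the model is plain multiple linear
regression by design — and the published table cannot be refit because
the underlying per-specimen measurements were never published in full.

## Evaluation

`max_coordinate_error` reports, per specimen, the per-axis maximum of
|predicted − measured| over all template points, with the achieving point
recorded; the clinically motivated acceptance threshold for the coronoid
region is 2 mm per axis. Two protocols: `insample` (fit on all n,
evaluate each — mirrors the original study's protocol and is the default)
and `loo` (leave-one-out — unbiased, recommended; requires n ≥ 3). For a
full-rank design with iid coordinate noise of SD σ, the in-sample
residual for specimen i has SD `σ·√(1−hᵢ)` and the leave-one-out error
`σ/√(1−hᵢ)` (leverage `hᵢ`, mean 11/n), so LOO maxima are systematically
and substantially larger than in-sample maxima; reports from the two
modes must not be compared against each other.

**Surface loft.** The original surfaces were built interactively in a CAD
package; the toolkit replaces this with a deterministic loft: a natural
cubic spline along each template row (chord-length parameter), linear
blending across rows, tessellated on a grid that always contains every
row's own knots, so the surface interpolates the input points exactly.
This is an approximation to CAD multisection surfacing, chosen for
reproducibility.

**Surface deviation.** Unsigned distance from densely sampled points of
the calculated surface to the reference mesh (direction:
calculated → reference, matching the headline metric's definition; a
symmetric variant is available). Sampling subdivides calculated-surface
triangles until no edge exceeds `max_edge` (default 0.5 mm, giving a
discretization error well below 0.05 mm for anatomically curved
surfaces). Point-to-mesh distances are exact point-triangle distances,
computed in-package (vectorized closest-point-on-triangle with a KD-tree
prefilter over triangle centroids and a certified widening pass), and
validated against dense barycentric sampling and analytic sphere offsets.

## Synthetic data

The generators define the study conditions for all simulation tests:

* **Parameter vectors** — uniform within per-parameter ranges. d1
  ∈ [28.5, 32.7], d9 ∈ [16.1, 24.3] and d10 ∈ [115.7, 136.3] mm reproduce
  the spread of the published example measurement columns; the remaining
  ranges (see `DEFAULT_PARAMETER_RANGES`) are standard adult mandibular
  anthropometry magnitudes (e.g. bigonial width 85–105 mm, bicondylar
  breadth 110–130 mm).
* **Ground-truth models** — coefficients uniform with published-scale
  magnitudes: intercepts in ±25 mm, slopes in ±3.
* **Coordinates** — model prediction plus independent isotropic Gaussian
  noise per coordinate (default SD 0.5 mm). The noise model is a choice
  (real landmark-measurement error is likely anisotropic and spatially
  correlated); it is configurable in principle and documented as the main
  gap between simulation and scan data.
* **Test solid** — a star-shaped blob (sphere with two superior lobes
  separated by a saddle notch, anisotropic scaling, posterior shear
  setting the ramus angle, default 125°, valid range 90–140°), watertight
  by construction, with all ten vocabulary landmarks planted as exact
  mesh vertices. It reproduces the geometric features the pipeline
  exercises — notch, processes, plantable landmarks, sectionable flange —
  and nothing else; it is not an anatomical mandible.

Default simulated population size is n = 30: comfortably overdetermined
for 11 coefficients, in contrast to the underdetermined n = 10 of the
original study, so that coefficient recovery and cross-validation are
well-posed. All generators are pure functions of their arguments and a
seed.

## What passing tests do and do not show

Noiseless-recovery, oracle-equivalence and invariance tests verify the
*implementation*: the solver returns the coefficients that generated the
data, the geometry is rigid-invariant, metrics agree with brute force.
The simulation tests verify *statistical behavior under the stated
generator* — linear truth, uniform parameters, iid Gaussian noise. None
of this certifies accuracy on real mandibles, where the true
point-coordinate/parameter relationship is not exactly linear and n is
small; the published in-sample errors (≤ 1.72 mm coordinate error,
≤ 1.36 mm surface deviation on ten specimens) remain the only available
real-data evidence.

A consequence worth stating explicitly: under the simulation conditions
(n = 30, σ = 0.5 mm, 117 responses, leave-one-out), the LOO error for one
coordinate has SD ≈ σ/√(1−h̄) ≈ 0.63 mm, and the *maximum* over the
≈ 17,500 coordinates examined across five seeds is therefore expected
near 2.6 mm. The acceptance simulation computes this maximum honestly and
reports values of ~2.5–3.0 mm — above the 2 mm per-axis clinical bound.
The bound is met by the in-sample protocol (SD ≈ σ·√(1−h̄), maxima
≈ 1.5–1.8 mm) and against noiseless ground truth, but not by the LOO
maximum against noisy measurements; with iid noise of SD 0.5 mm that is a
property of order statistics, not an implementation defect.

## Known limitations

* The OCS base-plane orientation from a single inferior landmark is a
  perpendicular-drop construction; with real scans a support-plane
  construction against the mesh would be anatomically closer.
* The loft blends linearly across rows; with only three rows the surface
  is at most piecewise-ruled in the transverse direction.
* Mesh-based parameter operationalizations (VTM/STM/MSR) are reasonable
  readings of prose definitions and are validated on synthetic solids of
  known dimensions, not against an anthropometric gold standard.
* Left/right sides are handled by a side switch, not by pooling mirrored
  data; whether the original model pooled sides is unknown.
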