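# Methods

## The parametric point model

A bone is represented by a *corresponded point cloud*: P surface points,
indexed so that point *i* marks the same anatomical location on every
specimen of a training set.  Given S specimens with clouds
`M_s ∈ R^{P×3}` and morphometric parameter vectors `d_s ∈ R^k` (scalar
dimensions measured on medical images, in mm), every coordinate of every
point is modelled as an affine function of the parameters:

    coord_{i,a}(d) = b_{i,a,0} + Σ_k b_{i,a,k} d_k ,   a ∈ {x, y, z}

All 3·P scalar regressions share the single design matrix
`X = [1, d_1, …, d_k]` (rows = specimens) and are solved jointly by
ordinary least squares.  The solver is a numerically stable least-squares
factorisation (`numpy.linalg.lstsq`), not an explicit normal-equations
inverse; the test suite carries an independent literal
`B = (XᵀX)⁻¹Xᵀy` oracle and checks agreement to 1e-8 relative on
randomised full-rank instances.

**Reduced-parameter models.**  When a patient's images only permit a subset
of the measurements, the model *refits* the regression on that subset's
columns rather than zeroing coefficients of the full fit — zeroing is not
the least-squares solution on the subset.  Every fitted subset is cached in
the model's coefficient store (key: sorted name tuple); prediction selects
the entry matching exactly the supplied parameter names and fits it on
demand when a training set is attached.  An intercept-only model
(`fit_intercept_model`) covers the single-specimen case: the "model" is the
mean (here: only) cloud.

**Rank handling.**  Fits require `S ≥ k+1`; the condition number of `XᵀX`
is checked against a ceiling (default 1e10) and exactly collinear
predictors are rejected with `RankDeficientError` — never silently
pseudo-inverted.  A per-bone minimum parameter count (default 1) guards
prediction from degenerate inputs.

**Model store.**  Models persist as versioned JSON text
(`"schema": "pbm-model/1"`), with coefficients serialised as shortest
round-trip decimals (load∘save is a bitwise identity on the tensors) and a
SHA-256 of the canonical payload for integrity.  Unknown schema versions
and corrupted files raise distinct errors.

## Surface reconstruction

Predicted clouds with a grid annotation (L slices × M points per slice) are
meshed by lofting: each slice gets a *periodic cubic interpolating spline*
with chord-length parameterisation, resampled uniformly by arc length;
consecutive rings are joined by quad strips split into triangles, ends are
closed by centroid fans.  The ring-to-ring correspondence rotates each
ring's start index to minimise total squared inter-ring distance (lowest
index wins ties), the analogue of a CAD multisection surface's coupling.
Capped lofts satisfy `V = L·n + 2`, `F = 2(L−1)n + 2n`, are watertight and
have Euler characteristic 2.  Collinear slices are rejected
(`DegenerateSliceError`); poorly matched consecutive rings raise a
`SelfIntersectionWarning` but do not abort.

Plane clipping keeps one side of an oriented plane (on-plane vertices, to
1e-9 mm, belong to the kept side), splits straddling triangles, and — for
watertight inputs — closes the planar cross-section.  The cross-section cap
is triangulated by a deterministic ear-clipper over the boundary loops of
the open cut: only strictly convex ears containing no other loop vertex are
clipped, so collinear boundary vertices remain in the triangulation and the
cap shares every boundary edge with the clipped surface (this is what makes
the result watertight).  Clipping front plus back reproduces the input
volume to better than 1e-6 relative.

Rigid rotations about an axis line use the Rodrigues form; they are exact
isometries (pairwise distances to 1e-9) and orientation-preserving.

## Plate design

The plate workflow mirrors the clinical construction: the surgeon picks
ordered anatomical points on the bone; an open interpolating spline through
them (arc-length resampled) is the *reference line*; bone points whose
distance to the line is at most the corridor half-width form the *contact
surface*.  Contact fidelity is strict: patch vertices are the bone's own
points, never resampled.  The corridor half-width has **no default** — it
is a clinical choice the plate designer must state explicitly.

Selected points are organised into a structured u×v grid: u is arc-length
projection onto the line, v the signed lateral offset (across-line
direction = tangent × mean radial offset).  u-levels are identified either
by exact rounding (corresponded grids share u values under a straight
line) or by splitting sorted u at gaps larger than `u_cluster_gap` mm — the
robust choice for curved reference lines; the fixture plate uses 10 mm
against a ~34 mm slice spacing.  Non-rectangular selections raise
`InsufficientCoverageError` rather than guessing a topology.

Solidification offsets each contact vertex by the plate thickness along its
outward unit normal (angle-weighted average of incident face normals,
oriented away from the bone centroid), then stitches side walls between the
boundary loops.  Every outer vertex is at Euclidean distance exactly equal
to the thickness from its contact counterpart (machine precision); on a
discretised cylinder the *interior* outer vertices sit at radius r+t
exactly, while boundary vertices deviate by the one-sided normal average
(~3e-3 mm at test geometry) — the offset-distance invariant still holds
there.  A thickness exceeding the local concave curvature radius flips
offset faces and raises `SelfIntersectionError`.

Screw holes are regular 64-gon prisms cut through reserved blocks of whole
grid cells, connected to the block perimeter by an angular two-pointer
annulus triangulation in parameter space.  This keeps watertightness
provable without a mesh-boolean kernel; the polygon-vs-circle area deficit
is 0.16 %.  Holes must fit strictly inside the patch interior
(`HoleOffPlateError`) and must not overlap (`HoleOverlapError`).  The
default thickness in the fixture spec is 3 mm, the value used for printed
reconstructive plates.

Export writes binary or ASCII STL (or PLY) plus a JSON manifest (spec,
source-bone hash, area/volume/bounds).  Binary STL output is byte-identical
for identical inputs; note STL stores float32, so re-read coordinates equal
the float32 cast of the originals.

## Temporomandibular axis reconstruction

When the condyles are missing from the 3D scan, the hinge axis is recovered
from a lateral X-ray.  In 2D (pixels converted to y-up mm via the etalon
scale factor `mm/px = etalon_mm / etalon_px`):

- mandibular line through menton (ME) and gonion (GO);
- occlusion line fitted to the incisal/cusp landmarks by **total least
  squares** (principal axis) — an ordinary y-on-x fit would not be
  invariant under image rotation, which the construction's distances must
  be;
- perpendiculars dropped from the surgeon-marked axis point to both lines;
  the signed foot distances are measured from ME (mandibular, along ME→GO)
  and from the most-anterior occlusion landmark (occlusion, oriented
  posteriorly).

In 3D the same construction uses the patient's occlusion and mandibular
*planes*: the in-plane sagittal directions are the plane∩sagittal
intersections (sagittal normal = cross of the two plane normals), the foot
distances are laid off from ME and from the 3D occlusion reference
landmark, and perpendicular planes erected at those feet intersect in the
axis line.  A single lateral view cannot constrain the axis direction, so
it is taken medio-lateral (perpendicular to the sagittal plane) — the
hinge-axis interpretation.  The frame carries an optional `occlusion_ref`
3D landmark; without it the projection of ME onto the occlusion plane is
used, which is consistent but less anatomically faithful.

On the synthetic forward model (orthographic lateral projection with
etalon, optional Gaussian pixel noise) the noise-free round trip recovers
the axis to ≤1e-12 mm / 0° — well inside the 0.1 mm / 0.1° budget; at
0.5 px landmark noise the error grows to the order of the scaled pixel
noise and is reported, not asserted.

Osteotomy planning clips the mandible with the left and right cut planes
(normals pointing toward the tooth-bearing segment), decomposed
sequentially so fragment volumes sum exactly to the input volume, and
rotates the freed segment about the axis by a surgeon-chosen angle (the
"good occlusion" angle is clinical judgement, not computed).

## Synthetic populations

Two families emulate scanned specimens with *exactly affine* dependence on
four parameters each, so the generating coefficient tensor is known:

- **tube** (long-bone): L elliptical sections along the long axis, a fixed
  3 mm anterior bow as intercept; parameters: length (330–420 mm) and
  proximal/midshaft/distal widths (65–85 / 22–32 / 40–55 mm), blended by a
  quadratic Lagrange basis.  Defaults S=8, L=12, M=16.
- **horseshoe** (mandible): a U centerline swept with an elliptical
  section, arms rising beyond ±45°; parameters: bigonial width
  (85–105 mm), arch depth (70–90 mm), ramus height (55–70 mm), body height
  (24–32 mm).  Defaults S=6, L=9, M=12.  Landmarks (ME, GO left/right) sit
  at fixed grid indices.

Noise is i.i.d. Gaussian per coordinate, default σ = 0.3 mm (sub-millimetre
surface error typical of segmented CT; correlated noise is deliberately
out of scope).  The RNG is numpy's PCG64, pinned by name in the config;
fixture regeneration is byte-identical for a given seed.  What passing
tests show about real data is limited accordingly: real bones are not
exactly affine in four dimensions, correspondence is not free, and noise
is spatially correlated — the generator validates the *machinery*
(estimation, geometry, invariants), not anatomical adequacy.

## Numerical choices and limitations

- Condition ceiling 1e10; clip on-plane tolerance 1e-9 mm; degenerate
  sliver faces below 1e-14 of the largest face are dropped after clipping.
- Arc-length resampling inverts a dense (≥2048-point) cumulative chord
  table; accuracy is far below the 0.05 mm curve budgets at the problem
  sizes used (hundreds of points per curve).
- Problem sizes throughout (S ≤ 200, P ≤ 320, 64 samples per ring) keep
  the full test suite and the acceptance script in the low seconds on one
  CPU; they were chosen as the smallest sizes at which every property is
  exercised with margin.
- No mesh booleans, remeshing, smoothing or self-intersection repair; no
  automatic correspondence or landmarking; no neural-network predictor; no
  mechanical analysis of plates.  Establishing anatomical correspondence
  across specimens is a *precondition* of the training container.
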