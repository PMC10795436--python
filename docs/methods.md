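# Methods

## Scope and data model

The package positions two daily organ surfaces (cervix, uterus) against
their planning references by a rigid couch-style correction. Inputs are
closed triangular meshes in LPS patient coordinates (millimetres); file
formats carry no unit metadata and values are taken as mm. Contour
extraction, mesh generation from contour stacks, and bone
co-registration are upstream of this package: meshes are assumed to
share one frame already.

Validation normalizes every mesh on ingest: vertices closer than
1e-6 mm are merged (union-find over k-d-tree pairs), every undirected
edge must be shared by exactly two faces (otherwise the mesh is
rejected naming a boundary edge), winding is made consistent by
propagation across shared edges and oriented outward by requiring
positive enclosed volume. Validation is idempotent.

## Geometry

**Containment** uses the generalized winding number (sum of signed
solid angles over all reference triangles, van Oosterom–Strackee),
thresholded at 1/2. Points whose winding number falls within 1e-3 of
the threshold and that are farther than 1e-6 mm from the surface fall
back to crossing-parity of a jittered ray (deterministically seeded).
Points within 1e-6 mm of the surface count as inside with distance 0,
so a perfectly matched organ has exactly zero cost.

**Distances** are exact minimum point-to-triangle distances (Voronoi
region closest-point computation), evaluated over all reference
triangles. The hot loops are numba-compiled scalar kernels; a
vectorized numpy path (with k-d-tree candidate pruning that provably
cannot change the minimum) is the portable fallback and the in-repo
reference. Tests compare both against trimesh's brute-force
closest-point query and an independently written ray-parity oracle.

**Rotations** are extrinsic fixed-axis, applied pitch (x), roll (y),
yaw (z), degrees, right-hand rule. The order is a convention: within
the clamped ±3° range the order effect is negligible, but one order
must be fixed for reproducibility. On-the-nose identities (pure
translations) bypass the rotation matrix so zero-rotation moves are
bit-exact.

## Cost

`Cost_organ = W_out·Σd²/i + W_in·ΣD²/t`, the weighted mean squared
surface distance of the outside and inside vertex groups; an empty
group contributes zero (0/0 := 0). The formula is applied literally:
strictly interior vertices incur cost even when the daily organ is
nested inside the reference, which penalizes over-shrunken or deeply
displaced configurations. Cost is additive across organs, each scored
against its own reference, homogeneous of degree one in each weight,
and invariant under a common rigid motion of daily and reference
meshes.

## Optimizer

Both organs move as one rigid body; translation is optimized first,
then rotation, each exactly once.

* Translation: the first candidate is the full pooled-centroid
  difference (reference minus daily), subject to the same accept/revert
  rule as every other move. Subsequent per-axis step magnitudes halve
  each iteration starting from half the centroid-shift components,
  clamped below at the 1 mm couch floor. At each magnitude the six
  signed axis moves are tried in fixed order (x+, x−, y+, y−, z+, z−),
  accepted greedily on strict decrease (relative tolerance 1e-9; ties
  revert), and the sweep repeats until it accepts nothing; a rejected
  full sweep at the floor ends the phase.
* Rotation: the same scheme with magnitudes 45°, 22.5°, … floored at
  0.5°, candidates ±pitch, ±yaw, ±roll about the pooled daily centroid
  fixed at the start of the phase.

The reported rotation is the Euler decomposition (package convention)
of the net accumulated rotation matrix, not the per-axis sum of
accepted increments: finite rotations do not commute, and the couch
delivers one net rotation. The optional clamp skips any candidate
whose decomposed net angles would exceed the limit on any axis — the
search never explores beyond the clamp rather than truncating
afterwards, so every reported configuration corresponds to an evaluated
cost. A clamp of zero therefore reproduces the translation-only result
bitwise.

Termination is guaranteed (strict decrease, cost bounded below, floor
stopping rule); a per-phase cap of 500 cost evaluations bounds runtime
on pathological inputs, flagging the trace and returning the best
position so far. Every attempted move is recorded (phase, magnitude
index M, commanded magnitude, axis, sign, costs, accepted/skipped), and
identical inputs yield bit-identical traces.

## PTV construction and coverage

Margins are applied to the reference (planning) meshes. Each vertex
moves outward along its area-weighted normal n by
`||(m_x n_x, m_y n_y, m_z n_z)||₂`, choosing per component the margin of
the direction the normal points to (R/L for x, A/P for y, I/S for z).
For an isotropic margin this reduces to a uniform normal offset; an
icosphere at subdivision 3 reproduces the analytic offset sphere within
2% radial error. The construction approximates a Minkowski sum with an
octant-wise ellipsoid; exact Minkowski expansion and watertight mesh
booleans are out of scope, so the PTV is represented by its containment
predicate — a point is inside iff it is inside either expanded organ
surface — and the exportable PTV mesh is the two shells concatenated,
for visualization only.

Coverage of a daily organ is the number of its vertices inside the PTV
divided by its total vertex count, reported per organ and pooled.
Positioning modes: translation only, or translation plus rotation
clamped at 3° (the couch tolerance). In cohort summaries the *reported*
rotations come from an unclamped rotational phase — the correction the
anatomy calls for, which can exceed the deliverable limit — while
coverage uses the clamped, deliverable rotation.

## Synthetic phantoms

The generator emulates the geometry and motion structure of the
clinical problem, not its images. Organs are superellipsoids
(exponent 2.5, i.e. squareness 0.8 — slightly boxy so rotations are
observable in the cost; spheres would make rotation about the centre a
no-op): cervix 15×15×20 mm; uterus 25×20×40 mm, anteverted 30° (long
axis tilted anteriorly from S-I) and stacked superior-anterior to the
cervix. Meshes come from radially mapping an icosphere, so they are
watertight by construction. The default subdivision level is 2
(162 vertices per organ), which keeps one full match under a second
while leaving the cost landscape stable; level 3 (≈640 vertices) is a
parameter away and is used in the denser oracle tests.

The daily pair is the reference pair moved by a known rigid transform
about the pooled centroid — so ground truth is exact — optionally
followed by a smooth band-limited radial deformation (three
organ-scale sinusoids along vertex normals, amplitude in mm, rejected
above 20% of the smallest semi-axis where self-intersection becomes
possible; volume changes stay within the first-order 3a/r bound).

Default motion sampling is anisotropic, mirroring reported
cervix/uterus inter-fraction motion: translation uniform with
half-widths (6, 12, 12) mm on (R-L, A-P, S-I) — so roughly a sixth of
fractions need >10 mm posterior/superior correction and essentially
none need it laterally — and rotation pitch-dominant, true pitch
uniform over [−6°, 14°] (the corrective pitch then has a negative
median), yaw and roll within ±1°. All widths and centres are
configurable; cohort seeds derive deterministically from one master
seed.

What the phantoms do *not* model: bladder/rectum-filling biomechanics,
contouring error, inter-observer variability, image noise, or the
vertex densities of clinical contour-to-mesh pipelines. Passing
recovery tests therefore demonstrates correctness of the cost and
search under known rigid truth with mild shape noise — not clinical
registration accuracy.

## Known limitations and numerical choices

* **Yaw–roll degeneracy.** For an anteverted uterus, small yaw (ε_z)
  and roll (ε_y) tip the long axis in the same direction to first order
  (weights sin τ and cos τ for tilt τ), leaving a curved valley in the
  cost that axis-aligned floor steps cannot traverse. Pure pitch — the
  clinically dominant rotation — is recovered within the 0.5° floor
  reliably; pure yaw likewise in all sampled cases; pure roll can stall
  with residuals up to about a degree even though the net orientation
  (and hence the cost) is essentially recovered. This mirrors the
  clinical observation that yaw/roll corrections are near zero while
  pitch carries the signal.
* **Greedy local search.** The dichotomy scheme is a deterministic
  coordinate descent; a large early move that decreases cost is kept
  even when globally suboptimal. No restarts or global optimizers are
  used, by design.
* **Interior-vertex penalty.** Following the cost formula literally, a
  daily organ strictly inside its reference has positive cost; the
  optimizer may therefore trade a small surface offset against deep
  containment.
* Acceptance tolerance for "decreased" is a relative 1e-9; exact ties
  revert. Dedup tolerance 1e-6 mm; on-surface tolerance 1e-6 mm;
  winding-number ambiguity band 1e-3.
* Problem sizes used in the shipped tests and the reproduction script
  (162-vertex organs, cohorts of ~25 fractions, 30–100 recovery
  phantoms) are the package defaults chosen to keep a full study run in
  minutes on one core; all sizes scale up by parameter.
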