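# Methods

## Scope and model overview

`needlesim` models dental-anesthesia needle insertion as a rigid straight
needle (tip plus exposed shaft) moving through a scene of closed triangle
meshes, each carrying a tissue-resistance model.  Three computations define
the engine: proximity/collision queries between the needle and the meshes,
a per-tissue elastic force response, and rule-based evaluation of the IANB
direct-technique task.  Everything is deterministic given its inputs and
explicit seeds; there is no hidden randomness and no wall-clock dependence,
so any recorded session replays to bit-identical results.

Units are millimetres, newtons and seconds throughout, in right-handed
coordinates.

## Synthetic anatomy

Real patient meshes can be loaded from OBJ/STL (via `trimesh`, with vertex
welding and removal of zero-area faces), but the package is fully testable
without them through two seeded generators.

**Slab phantom.**  An ordered list of `(tissue, thickness, k)` layers
becomes a stack of axis-aligned closed boxes tiling the insertion depth
along −z, the first surface at z = 0.  This is the standard layered-phantom
idealisation for validating force–depth curves: every layer boundary and
stiffness is known exactly, so the expected force curve can be written in
closed form.  The default three layers (mucosa 2 mm / muscle 10 mm / bone
8 mm at 0.35 / 0.6 / 4.0 N/mm) stand in for the soft-to-hard gradient the
needle meets in the real procedure.

**IANB scene.**  A stylised child hemi-mandible: a mucosa sheet
(y ∈ [3, 4]), a muscle volume (y ∈ [4, 10]), the ramus bone block
(y ∈ [10, 20]), and the inferior alveolar nerve as a vertical cylinder of
radius 1 mm at (x = 0, y = 9) descending to the mandibular foramen.  The
occlusal plane is z = 0 with normal +z.  For a child profile the foramen
landmark sits 2 mm *below* the occlusal plane (as it does anatomically in
children aged roughly 7–12); the adult profile places it at plane level.
Tongue, teeth and blood vessels are present as removable decorative
structures away from the insertion corridor; their placement carries small
seeded jitter so different seeds give distinct but equally valid scenes.
No published mandible dimensions back these numbers — they are declared
fixture defaults chosen to be plausible for a child ramus (~30 × 25 × 10 mm
block scale), not anatomical claims.  All generated meshes are watertight
with outward-consistent winding (verified in tests via `trimesh`), which is
what makes entering/exiting classification and inside/outside queries
well defined.

The target nerve can never be deactivated; at most one structure may be
flagged as the target nerve (the slab phantom has none, the IANB scene
exactly one — task evaluation requires it).

## Collision detection

A single octree spans all active structures; each triangle reference is a
`(structure, face)` pair, so one index serves proximity queries, crossing
extraction and logging.  Construction subdivides a node into exactly eight
octants by midpoint split, assigning a triangle to every child whose box
overlaps the triangle's bounding box (a conservative superset, harmless for
correctness).  Subdivision stops at a leaf capacity (default 16 triangles),
a maximum depth (default 10), or a minimum cell edge (default 1 mm).

Nearest queries run best-first branch-and-bound: octants are popped from a
priority queue ordered by the *exact* segment-to-box distance (zero if the
segment enters the box, else the minimum over both endpoints against the box
and the segment against the twelve box edges — exact because a
segment-interior/face-interior minimum only arises for face-parallel
segments, which the endpoint case covers) and pruned once their bound
exceeds the best triangle distance found.  Termination is therefore exact,
not epsilon-based, and the result provably equals the brute-force scan over
all triangles.  Both paths evaluate the same vectorised segment–triangle
distance kernel (intersection test, else the minimum over the two endpoints
against the triangle and the segment against the three edges), so agreement
is to floating-point precision; the test suite and the acceptance script
check ≥1000 random scene/segment pairs and observe deviations at the
10⁻¹⁵ mm level, far inside the 10⁻⁹ mm contract.

Ties between equidistant faces are broken toward the lexicographically
lowest `(structure, face)` in both paths (tie window 10⁻¹² mm) so results
are deterministic and comparable.

Surface crossings along a needle step are the step's intersections with the
indexed triangles, classified entering/exiting by the sign of the step
direction against the outward face normal, sorted by the parameter along
the step.  Grazing contacts (step parallel to the face) are not crossings;
coincident hits of one structure (shared edges/vertices of adjacent faces)
collapse to a single event.  For watertight meshes and trajectories that
start and end outside, entering and exiting events balance per structure — a
property test.

## Force model

**Axial.**  Hooke's law per tissue: `F = k (x0 − x1)` with `k` the tissue's
resistance constant (N/mm), `x0` the position of the tissue surface where
the needle entered it, and `x1` the current tip position, both along the
insertion axis (the step direction recorded at that entry).  Only the
tissue currently holding the tip contributes, and `x0` resets at every
crossing: the force–depth curve through a layered phantom is piecewise
linear, restarting at zero at each boundary with slope equal to the layer's
`k`.  The force is continuous from outside to inside at entry (both zero);
the value discontinuity at *internal* boundaries (restart at zero) is the
literal consequence of the per-tissue surface definition.  Whether
already-traversed superficial layers keep dragging on the shaft is left
unmodelled on purpose — the single-tissue reading is the simplest model
consistent with the per-structure resistance definition, and no data exists
here to fit a shaft-friction term.

**Lateral.**  Lateral force magnitude is `c · depth · offset`, directed
back toward the entry axis, with `c` = 0.01 N/mm² by default: zero at the
surface, growing linearly with insertion depth and with the tip's lateral
deviation, which captures the one stated qualitative requirement (lateral
forces increase with depth) with the fewest parameters.  Only monotonicity
is contractual; the linear form is a package design choice.

**Clamping and hard tissue.**  The total output is clamped to the device's
maximum renderable force (default 3.3 N, typical of the stylus-type haptic
devices used for such trainers; configurable).  Teeth and bone additionally
carry a yield force (defaults 3.0 / 2.5 N): once the axial Hooke force
reaches it, the tip is treated as blocked and the force plateaus — the
needle cannot be pushed through bone, it can only bend off it in reality,
and a plateau is the strongest statement a 3-DoF force model can make.

**Calibration.**  `calibrate_stiffness` fits `force = k · penetration` by
least squares through the origin and reports the RMS residual and the
slope's standard error.  On simulated data (n = 50, noise SD 0.05 N) the
recovery error is well inside three standard errors — the acceptance
contract.  Default per-structure constants (mucosa 0.35, muscles 0.6,
bones 4.0 N/mm, …) are placeholders for user calibration, not measured
tissue properties.

## Task evaluation

A `TaskSpec` holds: target angle 45° with ±10° tolerance (the clinical
instruction is "approximately 45 degrees"; ±10° is the package's
operationalisation), an entry zone (Euclidean disc of radius 4 mm around
the mucosal entry landmark — the projection of the foramen onto the outer
mucosa face), a depth window of 0.5–3 mm between tip and nerve surface, and
a nerve-contact prohibition.  The zone radius and window are configuration
defaults, not published values.

`evaluate_session` is a pure function of (log, scene, spec).  The entry
point is the first mucosa-entering event; the insertion angle is measured
between the occlusal plane and a short chord (~2 mm) of the trajectory from
the entry crossing — identical to the instantaneous direction for a straight
insertion and robust to sample-scale tremor.  Depth is assessed at the
deepest sample (maximal advance past the entry along the entry axis), so
retracting after a correct placement still passes — the training intent is
"did the tip reach the right spot", not "did it stay there".  A tip inside
or touching the nerve reads as distance zero (crossing-parity inside test
against the watertight nerve mesh).  Nerve contacts are counted from
entering events on the nerve structure.  Messages are emitted in a fixed
order (entry, angle, depth, nerve contact); the deposit-point success
message accompanies a passing depth check — actual anesthetic injection is
not simulated.

## Synthetic trainee trajectories

Four archetypes are generated from the scene's own landmarks, each a
straight approach from 6 mm outside the mucosa plus a smooth seeded lateral
bow ("tremor", amplitude `noise_sd` mm, zero at both endpoints so the entry
point and final depth stay exact):

* **ideal** — 45°, entry at the zone centre, stopping mid depth-window
  (1.75 mm from the nerve surface);
* **shallow** — same entry/angle, stopping 1 mm beyond the window
  (4 mm from the nerve): only the depth check fails;
* **wrong_angle** — 25° insertion reaching a correct depth: only the angle
  check fails;
* **nerve_hit** — correct entry and angle but overshooting 0.5 mm past the
  nerve surface: the nerve-contact check fails, and necessarily the depth
  check too, since the deepest sample lies inside the nerve (distance 0).

Stop depths are found by bisection on the tip-to-nerve distance along the
approach (after bracketing the closest approach on a coarse grid), so the
construction holds for any nerve geometry the scene provides.  The default
tremor amplitude used in tests and in the acceptance script is 0.1 mm; at
amplitudes much above ~0.2 mm the angle of the very short shallow insertion
becomes genuinely ill-determined, which is a physical statement about
1–2 mm insertions, not a numerical artefact.

## What the synthetic data does and does not show

The generators exercise every code path — layered force response, octree
queries on multiple watertight bodies, crossing parity, task discrimination
— under exactly known geometry, which is what makes the analytic force
curve and the archetype contracts checkable to 10⁻⁹.  They do not emulate
real anatomy: no curved tissue interfaces, no tissue deformation, no
patient variability beyond the child/adult foramen shift, and stylised
box/cylinder shapes instead of scanned meshes.  Passing tests therefore
validate the *engine* (geometry, bookkeeping, force law, evaluation logic),
not the clinical fidelity of any particular scene or stiffness table —
those must come from calibration against real devices and instructors.

## Numerical choices

* Parallel/coplanar classification tolerance 10⁻¹² (relative to geometry
  scale); boundary-inclusive barycentric tolerance 10⁻¹⁰ so edge and vertex
  touches count as hits.
* Distance ties broken lexicographically by `(structure, face)` within
  10⁻¹² mm.
* Coincident crossings of one structure merged within 10⁻⁹ mm along the
  step.
* Scene serialization is deterministic JSON (sorted keys, `repr`-exact
  floats), hashed (SHA-256, 16 hex chars) into a scene id that guards
  log/scene consistency at evaluation time; logs are JSON-lines with the
  same lossless float round-trip, so write→read→evaluate equals direct
  evaluation exactly.
* Problem sizes in tests and the acceptance script: 1000 random
  scene/segment pairs (20 soups of 50 triangles × 50 segments) for oracle
  equivalence, 347 samples for the slab force curve, 50 samples for
  calibration recovery — sizes at which the full suite completes in well
  under a minute while leaving the contracts exact.

## Known limitations

* The needle is rigid and straight; no bevel steering, bending or tissue
  deformation.
* 3-DoF force only (axial + lateral); no torque feedback.
* One tissue at a time exerts axial force; shaft drag from traversed layers
  is not modelled.
* Entry zone is a Euclidean disc, not a geodesic region on the mucosa.
* Hard-tissue blocking caps the force but does not alter the recorded
  trajectory (the trajectory is an input, not a simulated state).
* Injection/aspiration of the anesthetic is out of scope; the task ends at
  correct placement.
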