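# needlesim

A headless simulation engine for virtual-reality training of dental
anesthesia — specifically the **inferior alveolar nerve block (IANB)** by the
direct technique, the injection that numbs the lower jaw and is one of the
harder skills for dental students to acquire (clinical failure rates around
20–25 %). The engine reproduces the computational core of a haptic VR
trainer: the trainee advances a needle through the mucosa on the medial side
of the mandibular ramus at roughly 45° to the occlusal plane until the tip
sits next to the inferior alveolar nerve, without ever touching the nerve.

`needlesim` contains no graphics and no device driver; it is the part of
such a trainer that can be specified, tested and validated offline:

* **Anatomy scenes** (`needlesim.anatomy`) — named triangle-mesh structures
  (mucosa, muscles, bones, nerves, tongue, teeth, vessels) with per-tissue
  resistance models and task landmarks.  Two seeded generators provide
  complete synthetic scenes: a layered slab phantom and a stylised child
  hemi-mandible whose mandibular foramen sits slightly below the occlusal
  plane, as it does in children.
* **Collision detection** (`needlesim.collision`) — a shared octree over all
  active structures.  Nearest-triangle queries run as best-first
  branch-and-bound over octants and are *exactly* equivalent to an
  exhaustive brute-force scan (the built-in oracle).  Surface crossings
  along each needle step are classified entering/exiting from the watertight
  meshes' outward orientation.
* **Haptics** (`needlesim.haptics`) — per-tissue Hooke's-law axial
  resistance `F = k (x0 − x1)`, where `k` (N/mm) belongs to the tissue
  currently holding the tip and `x0`, `x1` are the tissue-surface and tip
  positions along the insertion axis; depth-proportional restoring lateral
  force; device-limit clamping; hard-tissue yield (bone cannot be
  penetrated); and least-squares stiffness calibration from
  force–displacement samples.
* **Task evaluation** (`needlesim.task`) — entry point, insertion angle
  (target 45°), depth window next to the nerve, and nerve-contact checks,
  each with user-facing messages.
* **Session logging** (`needlesim.session`) — deterministic replay of
  time-stamped trajectories, JSON-lines logs that round-trip losslessly,
  instructor summaries (training time, path length, structures traversed,
  contact counts), and seeded synthetic trainee trajectories
  (ideal / shallow / wrong-angle / nerve-hit archetypes).
* **CLI** (`needlesim`) — `gen-anatomy`, `run`, `validate`, `report`,
  `calibrate` subcommands; exit code 0 = pass, 1 = task failed, 2 = usage
  or I/O error.

## Worked example

```python
import needlesim as ns

scene = ns.generate_ianb_scene(seed=1, patient_profile="child")
traj = ns.generate_archetype_trajectory(scene, "wrong_angle", seed=3,
                                        noise_sd=0.1)
log = ns.run_session(scene, traj, ns.CalibrationTable.from_scene(scene))
result = ns.evaluate_session(log, scene, ns.TaskSpec.for_scene(scene))
print("\n".join(result.summary_lines()))
print("\n".join(ns.summarize(log).report_lines()))
```

prints

```
IANB task FAILED
  - Correct insertion point (0.3 mm from target).
  - Incorrect angle for insertion: 28.1 deg (target 45 deg +/- 10).
  - Correct depth: correct point to deposit the anesthetic solution (1.8 mm from the nerve).
  - No contact with the nerve.
training time: 3.90 s
needle path length: 9.61 mm
maximum insertion depth: 3.71 mm
structures traversed: mucosa, muscles
contacts with mucosa: 1
contacts with muscles: 1
```

The synthetic "wrong-angle" trainee entered at the correct mucosal spot and
reached a correct depth 1.8 mm from the nerve surface, but inserted at 28°
instead of ~45°, so only the angle check fails.  The same pipeline runs from
the shell:

```sh
needlesim gen-anatomy --seed 1 --profile child -o scene.json
needlesim run --scene scene.json --archetype ideal --seed 3 -o log.jsonl
needlesim validate --log log.jsonl --scene scene.json   # exit code 0
needlesim report --log log.jsonl
```

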