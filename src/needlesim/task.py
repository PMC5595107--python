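"""IANB direct-technique task specification and evaluation.

The trainee must insert the needle at the correct mucosal spot on the medial
side of the mandibular ramus, at approximately 45 degrees to the occlusal
plane, advancing until the tip sits next to the inferior alveolar nerve —
close enough for the anesthetic to reach it, without touching the nerve.

:func:`evaluate_session` replays a recorded session against a
:class:`TaskSpec` and produces a :class:`TaskResult` with one check per
criterion (entry point, angle, depth, nerve contact), each carrying the
measured value and a user-facing message.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .anatomy import Scene

DEFAULT_TARGET_ANGLE = 45.0
DEFAULT_ANGLE_TOLERANCE = 10.0
DEFAULT_ENTRY_RADIUS = 4.0
DEFAULT_DEPTH_WINDOW = (0.5, 3.0)

CHECK_ORDER = ("entry_point", "angle", "depth", "nerve_contact")


class TaskError(ValueError):
    pass


@dataclass
class TaskSpec:
    """Parameters of the IANB insertion task."""

    target_angle: float = DEFAULT_TARGET_ANGLE
    angle_tolerance: float = DEFAULT_ANGLE_TOLERANCE
    entry_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    entry_radius: float = DEFAULT_ENTRY_RADIUS
    depth_window: tuple[float, float] = DEFAULT_DEPTH_WINDOW
    forbid_nerve_contact: bool = True

    def __post_init__(self):
        self.entry_center = np.asarray(self.entry_center, dtype=float)
        if not 0 < self.target_angle < 90:
            raise TaskError("target_angle must be in (0, 90) degrees")
        if self.entry_radius <= 0:
            raise TaskError("entry_radius must be positive")
        lo, hi = self.depth_window
        if not (0 <= lo < hi):
            raise TaskError("depth_window must satisfy 0 <= min < max")

    @classmethod
    def for_scene(cls, scene: Scene, **kwargs) -> "TaskSpec":
        """Default task anchored at the scene's mucosal entry landmark."""
        if "entry_center" not in kwargs:
            if "entry_center" not in scene.landmarks:
                raise TaskError("scene has no entry_center landmark")
            kwargs["entry_center"] = scene.landmarks["entry_center"]
        return cls(**kwargs)

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "target_angle": self.target_angle,
            "angle_tolerance": self.angle_tolerance,
            "entry_center": self.entry_center.tolist(),
            "entry_radius": self.entry_radius,
            "depth_window": list(self.depth_window),
            "forbid_nerve_contact": self.forbid_nerve_contact,
        }, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TaskSpec":
        doc = yaml.safe_load(text)
        return cls(target_angle=doc["target_angle"],
                   angle_tolerance=doc["angle_tolerance"],
                   entry_center=np.array(doc["entry_center"]),
                   entry_radius=doc["entry_radius"],
                   depth_window=tuple(doc["depth_window"]),
                   forbid_nerve_contact=doc["forbid_nerve_contact"])

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_yaml(fh.read())


@dataclass
class CheckResult:
    passed: bool
    value: float | None
    message: str


@dataclass
class TaskResult:
    passed: bool
    checks: dict[str, CheckResult]
    messages: list[str]

    def summary_lines(self) -> list[str]:
        status = "PASSED" if self.passed else "FAILED"
        return [f"IANB task {status}"] + [f"  - {m}" for m in self.messages]


def insertion_angle(entry_direction, scene_or_normal) -> float:
    """Angle (degrees, in [0, 90]) between the needle and the occlusal plane.

    The angle to the plane is the complement of the angle to its normal:
    ``asin(|d · n|)`` for unit ``d`` and ``n``.
    """
    d = np.asarray(entry_direction, dtype=float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise TaskError("entry direction must be nonzero")
    d = d / nd
    if isinstance(scene_or_normal, Scene):
        n = scene_or_normal.occlusal_plane_normal
    else:
        n = np.asarray(scene_or_normal, dtype=float)
        n = n / np.linalg.norm(n)
    return float(np.degrees(np.arcsin(min(1.0, abs(float(d @ n))))))


def check_entry_point(entry_point, spec: TaskSpec) -> CheckResult:
    """Entry must fall within the Euclidean entry zone on the mucosa."""
    if entry_point is None:
        return CheckResult(False, None,
                           "No insertion: the needle never entered the "
                           "mucous membrane.")
    dist = float(np.linalg.norm(
        np.asarray(entry_point, dtype=float) - spec.entry_center))
    if dist <= spec.entry_radius:
        return CheckResult(True, dist,
                           f"Correct insertion point "
                           f"({dist:.1f} mm from target).")
    return CheckResult(False, dist,
                       f"Incorrect insertion point: {dist:.1f} mm from the "
                       f"target spot (allowed {spec.entry_radius:.1f} mm).")


def check_angle(angle_deg: float | None, spec: TaskSpec) -> CheckResult:
    if angle_deg is None:
        return CheckResult(False, None,
                           "No insertion: angle could not be measured.")
    if abs(angle_deg - spec.target_angle) <= spec.angle_tolerance:
        return CheckResult(True, angle_deg,
                           f"Correct insertion angle ({angle_deg:.1f} deg).")
    return CheckResult(False, angle_deg,
                       f"Incorrect angle for insertion: {angle_deg:.1f} deg "
                       f"(target {spec.target_angle:.0f} deg "
                       f"+/- {spec.angle_tolerance:.0f}).")


def tip_to_nerve_distance(tip, scene: Scene) -> float:
    """Distance (mm) from a tip position to the target-nerve surface.

    Zero when the tip touches or lies inside the nerve (surface meshes have
    no interior, so inside points are detected by crossing parity against
    the nerve's watertight surface).
    """
    from . import geometry as geo

    nerve = scene.target_nerve_name()
    if nerve is None:
        raise TaskError("scene has no target-nerve structure")
    mesh = scene.structures[nerve].mesh
    p = np.asarray(tip, dtype=float)
    tris = mesh.vertices[mesh.faces]
    closest = geo._point_triangles_closest(p, tris[:, 0], tris[:, 1],
                                           tris[:, 2])
    best = float(np.linalg.norm(p - closest, axis=1).min())
    if best > 0 and _point_inside_mesh(p, mesh):
        return 0.0
    return best


def _point_inside_mesh(p, mesh) -> bool:
    """Crossing-parity inside test against a watertight mesh."""
    from . import geometry as geo

    lo, _ = mesh.bounds()
    outside = lo - np.array([1.7, 2.3, 3.1])  # irregular ray to dodge edges
    crossings = 0
    for f in range(len(mesh.faces)):
        if geo.segment_triangle_intersection(p, outside,
                                             *mesh.triangle(f)) is not None:
            crossings += 1
    return crossings % 2 == 1


def check_depth(deepest_tip, scene: Scene, spec: TaskSpec) -> CheckResult:
    """Tip-to-nerve distance at the deepest point must fall in the window."""
    if deepest_tip is None:
        return CheckResult(False, None,
                           "No insertion: depth could not be measured.")
    dist = tip_to_nerve_distance(deepest_tip, scene)
    lo, hi = spec.depth_window
    if dist <= 0 and spec.forbid_nerve_contact:
        return CheckResult(False, dist,
                           "Contact of the needle with the nerve at the "
                           "deepest point.")
    if lo <= dist <= hi:
        return CheckResult(True, dist,
                           f"Correct depth: correct point to deposit the "
                           f"anesthetic solution "
                           f"({dist:.1f} mm from the nerve).")
    if dist > hi:
        return CheckResult(False, dist,
                           f"Insertion too shallow: needle tip {dist:.1f} mm "
                           f"from the nerve (must be within {hi:.1f} mm).")
    return CheckResult(False, dist,
                       f"Insertion too deep: needle tip {dist:.2f} mm from "
                       f"the nerve (must stay beyond {lo:.1f} mm).")


def check_nerve_contact(contact_count: int, spec: TaskSpec) -> CheckResult:
    if not spec.forbid_nerve_contact:
        return CheckResult(True, float(contact_count),
                           "Nerve contact not evaluated.")
    if contact_count == 0:
        return CheckResult(True, 0.0, "No contact with the nerve.")
    return CheckResult(False, float(contact_count),
                       f"Contact of the needle with the nerve "
                       f"({contact_count} time(s)).")


def evaluate_session(log, scene: Scene, spec: TaskSpec) -> TaskResult:
    """Evaluate a recorded session against the task specification.

    Pure function of (log, scene, spec): the entry point and angle are
    measured at the first mucosa crossing, the depth at the deepest sample
    along the insertion axis, and nerve contacts are counted from the
    recorded entering events on the target-nerve structure.
    """
    from .session import SessionLog  # local import to avoid a cycle

    if not isinstance(log, SessionLog) or not log.samples:
        raise TaskError("evaluate_session requires a non-empty session log")
    if log.scene_id and log.scene_id != scene.scene_id():
        raise TaskError(
            f"session log was recorded against scene {log.scene_id}, "
            f"not {scene.scene_id()}")

    entry_structure = "mucosa" if "mucosa" in scene.structures else "skin"
    entry_point = None
    entry_time = None
    for ev in log.events:
        if ev.structure == entry_structure and ev.kind == "entering":
            entry_point = np.array(ev.point)
            entry_time = ev.t
            break

    angle = None
    deepest_tip = None
    if entry_point is not None:
        # Direction of the step that produced the entry crossing.
        times = np.array([s.t for s in log.samples])
        idx = int(np.searchsorted(times, entry_time, side="right"))
        i0 = max(0, idx - 1)
        i1 = min(len(log.samples) - 1, max(idx, i0 + 1))
        step = np.array(log.samples[i1].tip) - np.array(log.samples[i0].tip)
        if np.linalg.norm(step) == 0:
            step = np.array(log.samples[i0].direction)
        axis = step / np.linalg.norm(step)
        # Deepest point: maximal advance past the entry along the entry axis.
        depths = np.array([(np.array(s.tip) - entry_point) @ axis
                           for s in log.samples])
        deepest_tip = np.array(log.samples[int(np.argmax(depths))].tip)
        # Insertion angle over a short chord from the entry crossing (the
        # needle orientation while advancing), robust to sample-scale tremor;
        # identical to the step direction for a straight insertion.
        chord_tip = deepest_tip
        for j in range(i0, len(log.samples)):
            if depths[j] >= 2.0:
                chord_tip = np.array(log.samples[j].tip)
                break
        chord = chord_tip - entry_point
        angle = insertion_angle(chord if np.linalg.norm(chord) > 0 else step,
                                scene)

    nerve = scene.target_nerve_name()
    contacts = sum(1 for ev in log.events
                   if ev.structure == nerve and ev.kind == "entering")

    checks = {
        "entry_point": check_entry_point(entry_point, spec),
        "angle": check_angle(angle, spec),
        "depth": check_depth(deepest_tip, scene, spec),
        "nerve_contact": check_nerve_contact(contacts, spec),
    }
    messages = [checks[name].message for name in CHECK_ORDER]
    passed = all(c.passed for c in checks.values())
    return TaskResult(passed=passed, checks=checks, messages=messages)
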