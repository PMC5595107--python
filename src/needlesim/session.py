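"""Session recording, replay, summarisation and synthetic trajectories.

A session steps a time-stamped needle trajectory through a scene, collecting
surface-crossing events and per-sample haptic forces into a
:class:`SessionLog` that serialises losslessly to JSON-lines.  The recorded
information covers the paths and angles of the needle, the structures it
traversed and how many times contact occurred, and the training time —
everything an instructor needs to review a trainee's attempt offline.

:func:`generate_archetype_trajectory` builds seeded synthetic student inputs
(ideal / shallow / wrong-angle / nerve-hit) from the scene's own landmarks,
standing in for device capture so the whole pipeline is testable headlessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import haptics as hx
from .anatomy import Scene
from .collision import build_octree, crossings_along_step
from .task import tip_to_nerve_distance

TRAJECTORY_COLUMNS = ["t", "x", "y", "z", "dx", "dy", "dz"]


class SessionError(ValueError):
    pass


@dataclass
class TrajectorySample:
    """One captured needle pose: time (s), tip (mm), unit direction."""

    t: float
    tip: tuple[float, float, float]
    direction: tuple[float, float, float]
    force: tuple[float, float, float, float] | None = None  # axial, lat xyz
    clamped: bool = False
    depth: float = 0.0
    tissue: str | None = None


@dataclass
class ContactEvent:
    t: float
    structure: str
    point: tuple[float, float, float]
    kind: str  # entering | exiting


@dataclass
class SessionLog:
    samples: list[TrajectorySample] = field(default_factory=list)
    events: list[ContactEvent] = field(default_factory=list)
    scene_id: str = ""
    seed: int = 0


def _unit(v):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise SessionError("zero direction vector in trajectory")
    return v / n


def read_trajectory_csv(path) -> list[TrajectorySample]:
    """Read a trajectory table (columns t,x,y,z,dx,dy,dz)."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SessionError(f"trajectory CSV missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        d = _unit((row.dx, row.dy, row.dz))
        out.append(TrajectorySample(float(row.t),
                                    (float(row.x), float(row.y),
                                     float(row.z)),
                                    tuple(float(c) for c in d)))
    return out


def write_trajectory_csv(samples, path) -> None:
    rows = [{"t": s.t, "x": s.tip[0], "y": s.tip[1], "z": s.tip[2],
             "dx": s.direction[0], "dy": s.direction[1],
             "dz": s.direction[2]} for s in samples]
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def run_session(scene: Scene, samples: list[TrajectorySample],
                calibration: hx.CalibrationTable,
                seed: int = 0) -> SessionLog:
    """Replay a trajectory through a scene, recording events and forces.

    Deterministic: identical inputs produce identical logs.  Raises for
    fewer than two samples or non-monotone timestamps.
    """
    if len(samples) < 2:
        raise SessionError("a session needs at least 2 trajectory samples")
    times = [s.t for s in samples]
    if any(t1 <= t0 for t0, t1 in zip(times, times[1:])):
        raise SessionError("timestamps must be strictly increasing")

    octree = build_octree(scene)
    state = hx.PenetrationState(tip=np.asarray(samples[0].tip, dtype=float))
    log = SessionLog(scene_id=scene.scene_id(), seed=seed)

    def record(sample, state, force):
        log.samples.append(TrajectorySample(
            t=sample.t, tip=sample.tip, direction=sample.direction,
            force=(force.axial, *np.asarray(force.lateral, dtype=float)),
            clamped=force.clamped, depth=state.total_depth,
            tissue=state.current_tissue))

    force = hx.total_feedback(state, calibration, scene)
    record(samples[0], state, force)
    prev = np.asarray(samples[0].tip, dtype=float)
    for i in range(1, len(samples)):
        cur = np.asarray(samples[i].tip, dtype=float)
        crossings = crossings_along_step(octree, prev, cur)
        t0, t1 = samples[i - 1].t, samples[i].t
        for c in crossings:
            log.events.append(ContactEvent(
                t=t0 + c.t * (t1 - t0), structure=c.structure,
                point=tuple(float(v) for v in c.point), kind=c.kind))
        state = hx.update_penetration(state, crossings, cur)
        force = hx.total_feedback(state, calibration, scene)
        record(samples[i], state, force)
        prev = cur
    return log


@dataclass
class SessionSummary:
    training_time: float
    path_length: float
    structures_traversed: list[str]
    contact_counts: dict[str, int]
    max_depth: float

    def report_lines(self) -> list[str]:
        lines = [
            f"training time: {self.training_time:.2f} s",
            f"needle path length: {self.path_length:.2f} mm",
            f"maximum insertion depth: {self.max_depth:.2f} mm",
            "structures traversed: "
            + (", ".join(self.structures_traversed) or "(none)"),
        ]
        for name in sorted(self.contact_counts):
            lines.append(f"contacts with {name}: {self.contact_counts[name]}")
        return lines


def summarize(log: SessionLog) -> SessionSummary:
    """Aggregate a session log into instructor-facing metrics."""
    if not log.samples:
        raise SessionError("cannot summarize an empty log")
    tips = np.array([s.tip for s in log.samples])
    path_length = float(np.sum(np.linalg.norm(np.diff(tips, axis=0), axis=1)))
    traversed = []
    counts: dict[str, int] = {}
    for ev in log.events:
        if ev.kind == "entering":
            counts[ev.structure] = counts.get(ev.structure, 0) + 1
            if ev.structure not in traversed:
                traversed.append(ev.structure)
    return SessionSummary(
        training_time=float(log.samples[-1].t - log.samples[0].t),
        path_length=path_length,
        structures_traversed=traversed,
        contact_counts=counts,
        max_depth=float(max(s.depth for s in log.samples)),
    )


# -- persistence (JSON lines, lossless float round-trip) ---------------------

def write_log(log: SessionLog, path) -> None:
    with open(path, "w") as fh:
        fh.write(json.dumps({"type": "meta", "format": "needlesim-log/1",
                             "scene_id": log.scene_id,
                             "seed": log.seed}) + "\n")
        for s in log.samples:
            fh.write(json.dumps({
                "type": "sample", "t": s.t, "tip": list(s.tip),
                "direction": list(s.direction),
                "force": list(s.force) if s.force is not None else None,
                "clamped": s.clamped, "depth": s.depth,
                "tissue": s.tissue}) + "\n")
        for ev in log.events:
            fh.write(json.dumps({
                "type": "event", "t": ev.t, "structure": ev.structure,
                "point": list(ev.point), "kind": ev.kind}) + "\n")


def read_log(path) -> SessionLog:
    log = SessionLog()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                kind = rec["type"]
                if kind == "meta":
                    if rec.get("format") != "needlesim-log/1":
                        raise KeyError("format")
                    log.scene_id = rec["scene_id"]
                    log.seed = rec["seed"]
                elif kind == "sample":
                    log.samples.append(TrajectorySample(
                        t=rec["t"], tip=tuple(rec["tip"]),
                        direction=tuple(rec["direction"]),
                        force=(tuple(rec["force"])
                               if rec["force"] is not None else None),
                        clamped=rec["clamped"], depth=rec["depth"],
                        tissue=rec["tissue"]))
                elif kind == "event":
                    log.events.append(ContactEvent(
                        t=rec["t"], structure=rec["structure"],
                        point=tuple(rec["point"]), kind=rec["kind"]))
                else:
                    raise KeyError("type")
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise SessionError(
                    f"{path}: malformed log record at line {lineno}: "
                    f"{exc}") from exc
    if not log.samples:
        raise SessionError(f"{path}: log contains no samples")
    return log


# -- synthetic student trajectories ------------------------------------------

ARCHETYPES = ("ideal", "shallow", "wrong_angle", "nerve_hit")


def _stop_depth_for_distance(scene, start, direction, target_dist,
                             max_advance=40.0):
    """Advance length at which the tip sits ``target_dist`` from the nerve.

    Bisection on the (monotone along the approach) tip-to-nerve surface
    distance; robust to any nerve shape the scene provides.
    """
    # Locate the closest approach first (distance is not monotone past it),
    # then bisect on the approaching half where it decreases monotonically.
    grid = np.linspace(0.0, max_advance, 201)
    dists = [tip_to_nerve_distance(start + s * direction, scene)
             for s in grid]
    i_min = int(np.argmin(dists))
    if dists[i_min] > target_dist:
        raise SessionError("trajectory never reaches the requested distance")
    lo, hi = 0.0, float(grid[i_min])
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if tip_to_nerve_distance(start + mid * direction,
                                 scene) - target_dist > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_archetype_trajectory(scene: Scene, archetype: str,
                                  seed: int = 0, noise_sd: float = 0.0,
                                  n_samples: int = 40,
                                  dt: float = 0.1) -> list[TrajectorySample]:
    """Seeded synthetic trainee trajectory realising one archetype.

    * ``ideal`` — entry at the zone centre, 45 deg to the occlusal plane,
      stopping with the tip inside the depth window next to the nerve;
    * ``shallow`` — same entry and angle, but stopping short of the window;
    * ``wrong_angle`` — 25 deg insertion reaching a correct depth;
    * ``nerve_hit`` — correct entry and angle but overshooting into the
      nerve.

    Hand tremor is emulated as a smooth seeded lateral bow of amplitude
    ``noise_sd`` mm, zero at both endpoints, so the realised entry point and
    final depth still define the archetype.
    """
    if archetype not in ARCHETYPES:
        raise SessionError(f"unknown archetype {archetype!r}")
    if "entry_center" not in scene.landmarks:
        raise SessionError("scene lacks the task landmarks")
    rng = np.random.default_rng(seed)
    entry = np.asarray(scene.landmarks["entry_center"], dtype=float)
    # In-plane approach direction: toward the tissue stack (+y in the
    # generated IANB scene), read from the foramen-entry geometry.
    approach = scene.landmarks["foramen"] - entry
    approach = approach - (approach @ scene.occlusal_plane_normal
                           ) * scene.occlusal_plane_normal
    approach = approach / np.linalg.norm(approach)
    down = -scene.occlusal_plane_normal

    angle = np.radians(25.0 if archetype == "wrong_angle" else 45.0)
    direction = np.cos(angle) * approach + np.sin(angle) * down
    window_lo, window_hi = 0.5, 3.0
    mid_window = 0.5 * (window_lo + window_hi)
    if archetype == "shallow":
        target = window_hi + 1.0
    elif archetype == "nerve_hit":
        target = 0.0
    else:
        target = mid_window
    advance = _stop_depth_for_distance(scene, entry, direction, target)
    if archetype == "nerve_hit":
        advance += 0.5  # push past the surface so a crossing is recorded

    if n_samples < 2:
        raise SessionError("need at least 2 samples")
    start = entry - 6.0 * direction
    end = entry + advance * direction
    ts = np.linspace(0.0, dt * (n_samples - 1), n_samples)
    u = np.linspace(0.0, 1.0, n_samples)
    pts = start[None, :] + u[:, None] * (end - start)[None, :]
    if noise_sd > 0:
        # smooth lateral bow perpendicular to the path, zero at endpoints
        perp = np.cross(direction, scene.occlusal_plane_normal)
        perp = _unit(perp)
        amp = rng.normal(0.0, noise_sd, size=2)
        bow = np.sin(np.pi * u)[:, None] * (
            amp[0] * perp + amp[1] * np.cross(direction, perp))[None, :]
        pts = pts + bow
    samples = []
    d = direction
    for i in range(n_samples):
        if i < n_samples - 1:
            d = _unit(pts[i + 1] - pts[i])
        samples.append(TrajectorySample(float(ts[i]),
                                        tuple(float(v) for v in pts[i]),
                                        tuple(float(v) for v in d)))
    return samples
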