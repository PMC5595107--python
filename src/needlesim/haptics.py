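"""Haptic force-feedback model for needle insertion.

The axial resistance follows Hooke's law per tissue,

    F = k (x0 − x1),

where ``k`` (N/mm) is the resistance constant of the tissue currently
holding the needle tip, and ``x0``/``x1`` are the positions of the tissue
surface (at entry) and of the tip along the insertion axis.  Only the
current tissue contributes: ``x0`` resets at every surface crossing, so the
force–depth curve through a layered phantom is piecewise linear, restarting
at zero at each boundary, with slope equal to the layer's ``k``.

Lateral force grows linearly with total insertion depth and with the tip's
lateral offset from the entry axis, restoring the tip toward that axis.  The
total output is clamped to the device's maximum renderable force.

Hard tissues (teeth, bone) carry a yield force: once the axial resistance
reaches it the tip is treated as blocked and the force plateaus — the
needle cannot be pushed through bone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .anatomy import Scene
from .collision import Crossing

#: default maximum renderable force (N) for the device class used
DEFAULT_DEVICE_MAX_FORCE = 3.3

#: default lateral-force coefficient (N/mm^2): force per mm depth per mm offset
DEFAULT_LATERAL_COEFF = 0.01


class HapticsError(ValueError):
    pass


@dataclass
class CalibrationTable:
    """Per-structure resistance constants plus device limits."""

    entries: dict[str, float] = field(default_factory=dict)
    device_max_force: float = DEFAULT_DEVICE_MAX_FORCE
    lateral_coefficient: float = DEFAULT_LATERAL_COEFF

    def __post_init__(self):
        if self.device_max_force <= 0:
            raise HapticsError("device_max_force must be positive")
        for name, k in self.entries.items():
            if k < 0:
                raise HapticsError(f"stiffness for {name!r} must be >= 0")

    @classmethod
    def from_scene(cls, scene: Scene, **kwargs) -> "CalibrationTable":
        """Seed the table from the scene's own tissue models."""
        return cls(entries={n: s.tissue.stiffness_k
                            for n, s in scene.structures.items()}, **kwargs)

    def stiffness_for(self, structure: str) -> float:
        if structure not in self.entries:
            raise HapticsError(
                f"structure {structure!r} missing from calibration table")
        return self.entries[structure]

    # calibration config round-trips as YAML
    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "device_max_force": self.device_max_force,
            "lateral_coefficient": self.lateral_coefficient,
            "resistances": dict(sorted(self.entries.items())),
        }, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CalibrationTable":
        doc = yaml.safe_load(text)
        return cls(entries=dict(doc.get("resistances", {})),
                   device_max_force=doc.get("device_max_force",
                                            DEFAULT_DEVICE_MAX_FORCE),
                   lateral_coefficient=doc.get("lateral_coefficient",
                                               DEFAULT_LATERAL_COEFF))

    def save(self, path):
        with open(path, "w") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_yaml(fh.read())


@dataclass
class ForceVector:
    """Axial + lateral haptic output; ``clamped`` marks device saturation."""

    axial: float
    lateral: np.ndarray
    clamped: bool = False

    def magnitude(self) -> float:
        return float(np.hypot(self.axial, np.linalg.norm(self.lateral)))


@dataclass
class PenetrationState:
    """Tissue bookkeeping for the needle tip.

    ``x0``/``x1`` are scalar coordinates along the insertion axis (the unit
    step direction recorded when the current tissue was entered), oriented so
    that advancing decreases the coordinate; penetration is ``x0 − x1 ≥ 0``.
    ``containment`` is the stack of structures currently holding the tip,
    innermost last.
    """

    tip: np.ndarray = field(default_factory=lambda: np.zeros(3))
    containment: tuple[str, ...] = ()
    entry_axes: dict[str, np.ndarray] = field(default_factory=dict)
    entry_points: dict[str, np.ndarray] = field(default_factory=dict)
    first_entry_point: np.ndarray | None = None
    first_entry_axis: np.ndarray | None = None
    layers_traversed: tuple[str, ...] = ()
    blocked: bool = False

    @property
    def current_tissue(self) -> str | None:
        return self.containment[-1] if self.containment else None

    @property
    def x0(self) -> float:
        cur = self.current_tissue
        if cur is None:
            return 0.0
        return -float(self.entry_points[cur] @ self.entry_axes[cur])

    @property
    def x1(self) -> float:
        cur = self.current_tissue
        if cur is None:
            return 0.0
        return -float(self.tip @ self.entry_axes[cur])

    @property
    def penetration(self) -> float:
        """Depth of the tip past the current tissue's surface (mm)."""
        return max(0.0, self.x0 - self.x1)

    @property
    def total_depth(self) -> float:
        """Depth of the tip past the first tissue surface entered (mm)."""
        if self.first_entry_point is None:
            return 0.0
        return max(0.0, float(
            (self.tip - self.first_entry_point) @ self.first_entry_axis))

    def lateral_offset(self) -> np.ndarray:
        """Tip displacement perpendicular to the entry axis (mm)."""
        if self.first_entry_point is None:
            return np.zeros(3)
        r = self.tip - self.first_entry_point
        return r - (r @ self.first_entry_axis) * self.first_entry_axis


def axial_resistance(k: float, x0: float, x1: float) -> float:
    """Hooke's law ``F = k (x0 − x1)`` for the current tissue."""
    if k < 0:
        raise HapticsError("k must be >= 0")
    if x1 > x0 + 1e-12:
        raise HapticsError("x1 must not exceed x0 (tip behind tissue surface)")
    return k * (x0 - x1)


def update_penetration(state: PenetrationState, crossings: list[Crossing],
                       tip, step_direction=None) -> PenetrationState:
    """Advance the tissue bookkeeping across one needle step.

    ``crossings`` must come from :func:`collision.crossings_along_step` for
    the step ending at ``tip``.  Entering a structure records the surface
    point and the step direction as that tissue's insertion axis; exiting
    pops it.  The first entry (from fully outside) anchors ``total_depth``
    and the lateral-offset axis; retracting fully outside resets the state.
    """
    tip = np.asarray(tip, dtype=float)
    new = replace(state, tip=tip,
                  containment=state.containment,
                  entry_axes=dict(state.entry_axes),
                  entry_points=dict(state.entry_points),
                  layers_traversed=state.layers_traversed)
    if step_direction is None:
        step = tip - state.tip
        n = np.linalg.norm(step)
        step_direction = step / n if n > 0 else None
    containment = list(state.containment)
    for c in crossings:
        if c.kind == "entering":
            if c.structure in containment:
                raise HapticsError(
                    f"re-entering {c.structure!r} while already inside")
            if step_direction is None:
                raise HapticsError("entering event on a zero-length step")
            containment.append(c.structure)
            new.entry_axes[c.structure] = step_direction
            new.entry_points[c.structure] = np.asarray(c.point, dtype=float)
            if len(containment) == 1 and new.first_entry_point is None:
                new.first_entry_point = np.asarray(c.point, dtype=float)
                new.first_entry_axis = step_direction
            new.layers_traversed = new.layers_traversed + (c.structure,)
        else:  # exiting
            if c.structure in containment:
                containment.remove(c.structure)
            new.entry_axes.pop(c.structure, None)
            new.entry_points.pop(c.structure, None)
    new.containment = tuple(containment)
    if not containment:
        # fully outside: reset the insertion anchor
        new.first_entry_point = None
        new.first_entry_axis = None
        new.blocked = False
    return new


def lateral_force(total_depth: float, tip_offset,
                  coefficient: float = DEFAULT_LATERAL_COEFF) -> np.ndarray:
    """Restoring lateral force: ``coefficient · depth · offset`` toward axis.

    Zero at zero depth or zero offset; magnitude strictly increasing in
    depth for fixed nonzero offset.
    """
    if total_depth < 0:
        raise HapticsError("total_depth must be >= 0")
    offset = np.asarray(tip_offset, dtype=float)
    return -coefficient * total_depth * offset


def total_feedback(state: PenetrationState,
                   calibration: CalibrationTable,
                   scene: Scene | None = None) -> ForceVector:
    """Full haptic output for the current penetration state.

    Axial Hooke force from the current tissue, restoring lateral force from
    the insertion depth and lateral offset, total magnitude clamped to the
    device maximum.  If ``scene`` is given and the current tissue has a
    yield force, the axial force plateaus there (blocked tip).
    """
    cur = state.current_tissue
    if cur is None:
        return ForceVector(0.0, np.zeros(3), clamped=False)
    k = calibration.stiffness_for(cur)
    axial = axial_resistance(k, state.x0, state.x1)
    if scene is not None and cur in scene.structures:
        yf = scene.structures[cur].tissue.yield_force
        if yf is not None and axial >= yf:
            axial = yf
            state.blocked = True
    lat = lateral_force(state.total_depth, state.lateral_offset(),
                        calibration.lateral_coefficient)
    total = float(np.hypot(axial, np.linalg.norm(lat)))
    if total > calibration.device_max_force:
        scale = calibration.device_max_force / total
        return ForceVector(axial * scale, lat * scale, clamped=True)
    return ForceVector(axial, lat, clamped=False)


@dataclass
class StiffnessFit:
    """Least-squares through-origin slope fit of force vs penetration."""

    k: float
    residual_rms: float
    stderr: float
    n: int


def calibrate_stiffness(samples) -> StiffnessFit:
    """Estimate a tissue's Hooke constant from (penetration, force) samples.

    Fits ``force = k · penetration`` by least squares through the origin and
    reports the RMS residual and the standard error of the slope.
    """
    arr = np.asarray(samples, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise HapticsError("need >= 2 (penetration, force) samples")
    pen, force = arr[:, 0], arr[:, 1]
    sxx = float(pen @ pen)
    if sxx <= 0 or np.allclose(pen, pen[0]):
        raise HapticsError("penetrations must not all be equal")
    k = float(pen @ force) / sxx
    resid = force - k * pen
    n = len(arr)
    dof = max(n - 1, 1)
    sigma2 = float(resid @ resid) / dof
    return StiffnessFit(k=k, residual_rms=float(np.sqrt(sigma2)),
                        stderr=float(np.sqrt(sigma2 / sxx)), n=n)
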