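"""Anatomical scenes and seeded synthetic phantoms.

A :class:`Scene` holds named anatomical structures (triangle mesh + tissue
resistance model + active flag) plus the landmarks the IANB task needs: the
occlusal plane (angular reference for the insertion), the mandibular-foramen
landmark on the medial ramus surface, and the mucosal entry point.

Two generators make every downstream stage testable without external data:

* :func:`generate_slab_phantom` — a stack of axis-aligned tissue boxes
  (e.g. mucosa / muscle / bone) tiling the insertion depth, the standard
  layered-phantom idealisation used to validate force–depth curves.
* :func:`generate_ianb_scene` — a stylised child (or adult) hemi-mandible
  scene: mucosa sheet over the medial ramus, a muscle volume, the ramus bone
  block, and the inferior alveolar nerve as a cylinder next to the foramen.
  For a child patient the foramen sits slightly below the occlusal plane;
  for an adult it sits at plane level.

Units are millimetres throughout, right-handed coordinates.  The nominal
insertion axis points toward the tissue along −z for the slab phantom and
along +y (toward the medial ramus surface) for the IANB scene.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

# The structure inventory modelled in the simulator.
STRUCTURE_INVENTORY = (
    "skin", "mucosa", "tongue", "gums", "teeth", "bones", "muscles", "nerves",
    "blood_vessels",
)


class SceneError(ValueError):
    """Raised for invalid scene construction or mutation."""


@dataclass
class TriangleMesh:
    """An indexed triangle mesh in millimetres.

    Invariants (enforced by :meth:`validate`): all face indices in range,
    finite coordinates, no zero-area faces.
    """

    name: str
    vertices: np.ndarray  # (n, 3) float64
    faces: np.ndarray     # (m, 3) int64

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)

    def validate(self, drop_degenerate: bool = False) -> "TriangleMesh":
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise SceneError(f"{self.name}: vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise SceneError(f"{self.name}: faces must be (m, 3)")
        if len(self.faces) == 0:
            raise SceneError(f"{self.name}: empty mesh")
        if not np.isfinite(self.vertices).all():
            raise SceneError(f"{self.name}: non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise SceneError(f"{self.name}: face index out of range")
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        degenerate = areas <= 1e-12
        if degenerate.any():
            if not drop_degenerate:
                raise SceneError(
                    f"{self.name}: {int(degenerate.sum())} degenerate faces")
            logger.info("%s: dropped %d degenerate faces",
                        self.name, int(degenerate.sum()))
            self.faces = self.faces[~degenerate]
            if len(self.faces) == 0:
                raise SceneError(f"{self.name}: empty mesh after cleanup")
        return self

    def triangle(self, face_index: int) -> np.ndarray:
        """The (3, 3) vertex array of one face."""
        return self.vertices[self.faces[face_index]]

    def face_normal(self, face_index: int) -> np.ndarray:
        a, b, c = self.triangle(face_index)
        n = np.cross(b - a, c - a)
        return n / np.linalg.norm(n)

    def bounds(self):
        return self.vertices.min(axis=0), self.vertices.max(axis=0)

    def __eq__(self, other):
        return (isinstance(other, TriangleMesh) and self.name == other.name
                and np.array_equal(self.vertices, other.vertices)
                and np.array_equal(self.faces, other.faces))


@dataclass
class TissueModel:
    """Per-structure resistance model.

    ``stiffness_k`` is the Hooke constant in N/mm.  ``yield_force`` (N), if
    set, marks a hard tissue (teeth, bone): the needle cannot penetrate past
    the depth at which the axial force reaches that value.
    """

    name: str
    stiffness_k: float
    is_target_nerve: bool = False
    is_removable: bool = True
    yield_force: float | None = None

    def __post_init__(self):
        if self.stiffness_k < 0:
            raise SceneError(f"{self.name}: stiffness_k must be >= 0")


@dataclass
class Structure:
    mesh: TriangleMesh
    tissue: TissueModel
    active: bool = True


@dataclass
class Scene:
    """Named anatomical structures plus task landmarks."""

    structures: dict[str, Structure] = field(default_factory=dict)
    occlusal_plane_point: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    occlusal_plane_normal: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    landmarks: dict[str, np.ndarray] = field(default_factory=dict)
    patient_profile: str = "child"
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.occlusal_plane_point = np.asarray(
            self.occlusal_plane_point, dtype=float)
        n = np.asarray(self.occlusal_plane_normal, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isclose(nn, 1.0, atol=1e-9):
            raise SceneError("occlusal plane normal must be unit length")
        self.occlusal_plane_normal = n / nn

    # -- structure management ------------------------------------------------

    def add_structure(self, mesh: TriangleMesh, tissue: TissueModel,
                      active: bool = True) -> None:
        if mesh.name in self.structures:
            raise SceneError(f"duplicate structure name {mesh.name!r}")
        if tissue.is_target_nerve and self.target_nerve_name() is not None:
            raise SceneError("scene already has a target nerve structure")
        mesh.validate()
        self.structures[mesh.name] = Structure(mesh, tissue, active)

    def target_nerve_name(self) -> str | None:
        for name, s in self.structures.items():
            if s.tissue.is_target_nerve:
                return name
        return None

    def active_structures(self) -> dict[str, Structure]:
        return {n: s for n, s in self.structures.items() if s.active}

    def signed_height_above_occlusal_plane(self, point) -> float:
        """Signed distance of a point above (+) / below (−) the plane."""
        return float((np.asarray(point, dtype=float)
                      - self.occlusal_plane_point) @ self.occlusal_plane_normal)

    def validate(self) -> "Scene":
        nerve_count = sum(
            s.tissue.is_target_nerve for s in self.structures.values())
        if nerve_count > 1:
            raise SceneError("at most one target-nerve structure allowed")
        if self.patient_profile == "child" and "foramen" in self.landmarks:
            if self.signed_height_above_occlusal_plane(
                    self.landmarks["foramen"]) >= 0:
                raise SceneError(
                    "child-profile foramen must lie below the occlusal plane")
        return self

    # -- serialization -------------------------------------------------------

    def to_text(self) -> str:
        """Lossless deterministic JSON serialization of the whole scene."""
        doc = {
            "format": "needlesim-scene/1",
            "patient_profile": self.patient_profile,
            "seed": self.seed,
            "occlusal_plane": {
                "point": self.occlusal_plane_point.tolist(),
                "normal": self.occlusal_plane_normal.tolist(),
            },
            "landmarks": {k: np.asarray(v, dtype=float).tolist()
                          for k, v in sorted(self.landmarks.items())},
            "metadata": self.metadata,
            "structures": [
                {
                    "name": name,
                    "active": s.active,
                    "tissue": {
                        "name": s.tissue.name,
                        "stiffness_k": s.tissue.stiffness_k,
                        "is_target_nerve": s.tissue.is_target_nerve,
                        "is_removable": s.tissue.is_removable,
                        "yield_force": s.tissue.yield_force,
                    },
                    "vertices": s.mesh.vertices.tolist(),
                    "faces": s.mesh.faces.tolist(),
                }
                for name, s in self.structures.items()
            ],
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    @classmethod
    def from_text(cls, text: str) -> "Scene":
        doc = json.loads(text)
        if doc.get("format") != "needlesim-scene/1":
            raise SceneError("not a needlesim scene document")
        scene = cls(
            occlusal_plane_point=np.array(doc["occlusal_plane"]["point"]),
            occlusal_plane_normal=np.array(doc["occlusal_plane"]["normal"]),
            landmarks={k: np.array(v) for k, v in doc["landmarks"].items()},
            patient_profile=doc["patient_profile"],
            seed=doc["seed"],
            metadata=doc.get("metadata", {}),
        )
        for rec in doc["structures"]:
            t = rec["tissue"]
            scene.add_structure(
                TriangleMesh(rec["name"], np.array(rec["vertices"]),
                             np.array(rec["faces"])),
                TissueModel(t["name"], t["stiffness_k"], t["is_target_nerve"],
                            t["is_removable"], t["yield_force"]),
                active=rec["active"],
            )
        return scene.validate()

    def scene_id(self) -> str:
        """Stable content hash used to guard log/scene consistency."""
        import hashlib
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_text())

    @classmethod
    def load(cls, path) -> "Scene":
        with open(path) as fh:
            return cls.from_text(fh.read())


def set_structure_active(scene: Scene, name: str, active: bool) -> Scene:
    """Toggle a structure; the target nerve cannot be deactivated.

    Mutates ``scene`` in place and returns it.  Inactive structures are
    excluded from collision, force and traversal computations.
    """
    if name not in scene.structures:
        raise SceneError(f"unknown structure {name!r}")
    s = scene.structures[name]
    if not active and s.tissue.is_target_nerve:
        raise SceneError("the target nerve structure cannot be deactivated")
    if not active and not s.tissue.is_removable:
        raise SceneError(f"structure {name!r} is not removable")
    s.active = active
    return scene


# -- mesh primitives ---------------------------------------------------------

_BOX_FACES = np.array([
    [0, 2, 1], [1, 2, 3],   # z = lo (normal −z)
    [4, 5, 6], [5, 7, 6],   # z = hi (normal +z)
    [0, 1, 4], [1, 5, 4],   # y = lo (normal −y)
    [2, 6, 3], [3, 6, 7],   # y = hi (normal +y)
    [0, 4, 2], [2, 4, 6],   # x = lo (normal −x)
    [1, 3, 5], [3, 7, 5],   # x = hi (normal +x)
], dtype=np.int64)


def box_mesh(name: str, lo, hi) -> TriangleMesh:
    """Closed axis-aligned box with outward-oriented faces."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(hi <= lo):
        raise SceneError("box_mesh requires hi > lo on every axis")
    verts = np.array([[hi[0] if i & 1 else lo[0],
                       hi[1] if i & 2 else lo[1],
                       hi[2] if i & 4 else lo[2]] for i in range(8)])
    return TriangleMesh(name, verts, _BOX_FACES.copy()).validate()


def cylinder_mesh(name: str, base, axis, length: float, radius: float,
                  sections: int = 16) -> TriangleMesh:
    """Closed cylinder from ``base`` along unit ``axis``, outward faces."""
    base = np.asarray(base, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # Build an orthonormal frame around the axis.
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    ang = 2 * np.pi * np.arange(sections) / sections
    ring = radius * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))
    bottom = base + ring
    top = base + length * axis + ring
    verts = np.vstack([bottom, top, base[None, :],
                       (base + length * axis)[None, :]])
    n = sections
    faces = []
    for i in range(n):
        j = (i + 1) % n
        # side quad (outward): bottom_i, bottom_j, top_i / bottom_j, top_j, top_i
        faces.append([i, j, n + i])
        faces.append([j, n + j, n + i])
        # caps: bottom center 2n, top center 2n+1
        faces.append([2 * n, j, i])
        faces.append([2 * n + 1, n + i, n + j])
    return TriangleMesh(name, verts, np.array(faces, dtype=np.int64)).validate()


# -- generators --------------------------------------------------------------

def generate_slab_phantom(layer_specs, lateral_size: float = 20.0,
                          seed: int = 0) -> Scene:
    """Layered tissue phantom: a stack of boxes along the −z insertion axis.

    ``layer_specs`` is an ordered list of ``(tissue_name, thickness_mm,
    stiffness_k)`` triples, outermost layer first.  The outer surface of the
    first layer lies at z = 0; layer *i* occupies depth
    ``[sum(thickness[:i]), sum(thickness[:i+1])]`` measured downward.
    Deterministic given ``seed`` (the seed is recorded for provenance; the
    geometry is fully determined by the specs).
    """
    if not layer_specs:
        raise SceneError("at least one layer required")
    scene = Scene(patient_profile="phantom", seed=int(seed),
                  occlusal_plane_point=np.zeros(3),
                  occlusal_plane_normal=np.array([0.0, 0.0, 1.0]))
    half = lateral_size / 2.0
    z_top = 0.0
    for tissue_name, thickness, k in layer_specs:
        if thickness <= 0:
            raise SceneError(
                f"layer {tissue_name!r}: thickness must be positive")
        z_bot = z_top - thickness
        mesh = box_mesh(tissue_name, (-half, -half, z_bot),
                        (half, half, z_top))
        scene.add_structure(mesh, TissueModel(tissue_name, float(k)))
        z_top = z_bot
    scene.metadata["kind"] = "slab_phantom"
    scene.metadata["total_depth_mm"] = -z_top
    scene.landmarks["entry_center"] = np.array([0.0, 0.0, 0.0])
    return scene.validate()


# Default resistance constants (N/mm) for the stylised scene.  Placeholder
# calibration values: users calibrate them per structure.
DEFAULT_STIFFNESS = {
    "skin": 0.30, "mucosa": 0.35, "tongue": 0.20, "gums": 0.50,
    "teeth": 5.0, "bones": 4.0, "muscles": 0.60, "nerves": 0.80,
    "blood_vessels": 0.25,
}


def generate_ianb_scene(seed: int = 0, patient_profile: str = "child") -> Scene:
    """Stylised hemi-mandible scene for the IANB direct-technique task.

    Geometry (mm, right-handed; needle approaches along +y toward the medial
    ramus surface):

    * occlusal plane: z = 0, normal +z;
    * mucosa sheet over the medial ramus: y ∈ [3, 4];
    * muscle volume between mucosa and bone: y ∈ [4, 10];
    * ramus bone block: y ∈ [10, 20];
    * inferior alveolar nerve: vertical cylinder, axis x = 0, y = 9,
      radius 1, z ∈ [−15, −1], running down to the mandibular foramen;
    * foramen landmark on the medial bone face (0, 10, z_f) with
      z_f = −2 for a child (slightly below the occlusal plane) and 0 for
      an adult;
    * mucosal entry landmark: the foramen projected onto the outer mucosa
      face, (0, 3, z_f).

    Decorative structures (tongue, teeth, gums, blood vessels) are present
    in the inventory but off the task path; their placement takes small
    seeded jitter so distinct seeds give distinct (but equally valid) scenes.
    """
    if patient_profile not in ("child", "adult"):
        raise SceneError(f"unknown patient profile {patient_profile!r}")
    rng = np.random.default_rng(seed)
    scene = Scene(patient_profile=patient_profile, seed=int(seed),
                  occlusal_plane_point=np.zeros(3),
                  occlusal_plane_normal=np.array([0.0, 0.0, 1.0]))
    z_foramen = -2.0 if patient_profile == "child" else 0.0
    nerve_radius = 1.0
    nerve_axis_xy = np.array([0.0, 9.0])

    scene.add_structure(
        box_mesh("mucosa", (-15.0, 3.0, -20.0), (15.0, 4.0, 10.0)),
        TissueModel("mucosa", DEFAULT_STIFFNESS["mucosa"]))
    scene.add_structure(
        box_mesh("muscles", (-15.0, 4.0, -20.0), (15.0, 10.0, 10.0)),
        TissueModel("muscles", DEFAULT_STIFFNESS["muscles"]))
    scene.add_structure(
        box_mesh("bones", (-15.0, 10.0, -20.0), (15.0, 20.0, 10.0)),
        TissueModel("bones", DEFAULT_STIFFNESS["bones"], is_removable=False,
                    yield_force=2.5))
    scene.add_structure(
        cylinder_mesh("nerves",
                      base=(nerve_axis_xy[0], nerve_axis_xy[1], -15.0),
                      axis=(0.0, 0.0, 1.0), length=14.0, radius=nerve_radius),
        TissueModel("nerves", DEFAULT_STIFFNESS["nerves"],
                    is_target_nerve=True, is_removable=False))

    # Decorative structures, off the insertion path (x < -8 or z > 5).
    jitter = rng.uniform(-0.5, 0.5, size=3)
    scene.add_structure(
        box_mesh("tongue", (-14.0 + jitter[0], -6.0, -18.0),
                 (-9.0 + jitter[0], 2.0, -6.0)),
        TissueModel("tongue", DEFAULT_STIFFNESS["tongue"]))
    scene.add_structure(
        box_mesh("teeth", (-14.0, 10.5 + jitter[1], 0.0),
                 (-9.0, 13.5 + jitter[1], 6.0)),
        TissueModel("teeth", DEFAULT_STIFFNESS["teeth"], yield_force=3.0))
    scene.add_structure(
        cylinder_mesh("blood_vessels",
                      base=(6.0 + jitter[2], 7.0, -18.0),
                      axis=(0.0, 0.0, 1.0), length=10.0, radius=0.6),
        TissueModel("blood_vessels", DEFAULT_STIFFNESS["blood_vessels"]))

    scene.landmarks["foramen"] = np.array([0.0, 10.0, z_foramen])
    scene.landmarks["entry_center"] = np.array([0.0, 3.0, z_foramen])
    scene.landmarks["nerve_base"] = np.array(
        [nerve_axis_xy[0], nerve_axis_xy[1], -15.0])
    scene.landmarks["nerve_tip"] = np.array(
        [nerve_axis_xy[0], nerve_axis_xy[1], -1.0])
    scene.metadata["kind"] = "ianb"
    scene.metadata["nerve_radius_mm"] = nerve_radius
    return scene.validate()


# -- mesh I/O ----------------------------------------------------------------

def load_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Load an OBJ or STL file into a validated :class:`TriangleMesh`.

    Degenerate faces are dropped with a logged count; duplicate vertices
    (e.g. from STL's per-facet storage) are welded.
    """
    import os

    import trimesh

    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in ("obj", "stl"):
        raise SceneError(f"unknown mesh format {fmt!r}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, force="mesh", process=True)
    except Exception as exc:
        raise SceneError(f"cannot read mesh {path}: {exc}") from exc
    if tm.is_empty or len(tm.faces) == 0:
        raise SceneError(f"empty mesh: {path}")
    name = os.path.splitext(os.path.basename(str(path)))[0]
    mesh = TriangleMesh(name, np.asarray(tm.vertices, dtype=float),
                        np.asarray(tm.faces, dtype=np.int64))
    return mesh.validate(drop_degenerate=True)


def save_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as OBJ or STL (via trimesh)."""
    import os

    import trimesh

    if fmt is None:
        fmt = os.path.splitext(str(path))[1].lstrip(".").lower()
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces,
                         process=False)
    tm.export(str(path), file_type=fmt.lower())
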