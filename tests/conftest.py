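import numpy as np
import pytest

import needlesim as ns
from needlesim.anatomy import Scene, TissueModel, TriangleMesh

#: slab layers used across force-model tests: (tissue, thickness mm, k N/mm)
SLAB_LAYERS = [("mucosa", 2.0, 0.35), ("muscles", 10.0, 0.6),
               ("bones", 8.0, 4.0)]


@pytest.fixture
def slab_scene():
    return ns.generate_slab_phantom(SLAB_LAYERS, lateral_size=20.0, seed=0)


@pytest.fixture
def ianb_scene():
    return ns.generate_ianb_scene(seed=1, patient_profile="child")


@pytest.fixture
def calibration(ianb_scene):
    return ns.CalibrationTable.from_scene(ianb_scene)


def random_soup_scene(rng, n_tri=50, extent=10.0):
    """Unstructured triangle-soup scene for oracle-equivalence checks."""
    scene = Scene(patient_profile="phantom")
    pts = rng.uniform(-extent, extent, size=(n_tri, 3, 3))
    mesh = TriangleMesh("soup", pts.reshape(-1, 3),
                        np.arange(n_tri * 3).reshape(-1, 3))
    scene.add_structure(mesh, TissueModel("soup", 0.1))
    return scene


def random_segment(rng, extent=12.0):
    while True:
        tip = rng.uniform(-extent, extent, 3)
        tail = rng.uniform(-extent, extent, 3)
        if not np.allclose(tip, tail):
            return ns.NeedleSegment(tip, tail)
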