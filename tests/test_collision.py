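"""Octree construction, nearest queries vs the brute-force oracle, crossings."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import needlesim as ns
from needlesim.anatomy import Scene, SceneError, TissueModel, TriangleMesh
from .conftest import random_segment, random_soup_scene


class TestOctreeStructure:
    def test_subdividing_a_node_yields_exactly_eight_octants(self, ianb_scene):
        octree = ns.build_octree(ianb_scene, max_depth=1)
        children = octree.subdivide_node(octree.root)
        assert len(children) == 8

    def test_children_partition_parent_bounds(self, ianb_scene):
        octree = ns.build_octree(ianb_scene)
        node = octree.root
        assert not node.is_leaf
        lows = np.stack([c.lo for c in node.children])
        highs = np.stack([c.hi for c in node.children])
        np.testing.assert_allclose(lows.min(axis=0), node.lo)
        np.testing.assert_allclose(highs.max(axis=0), node.hi)
        volumes = np.prod(highs - lows, axis=1)
        parent_volume = np.prod(node.hi - node.lo)
        assert volumes.sum() == pytest.approx(parent_volume)

    def test_single_triangle_under_capacity_root_is_leaf(self):
        scene = Scene(patient_profile="phantom")
        mesh = TriangleMesh("tri", np.eye(3), np.array([[0, 1, 2]]))
        scene.add_structure(mesh, TissueModel("tri", 0.1))
        octree = ns.build_octree(scene, leaf_capacity=4)
        assert octree.root.is_leaf
        assert octree.depth == 1

    def test_every_overlapping_triangle_referenced_by_leaf(self):
        rng = np.random.default_rng(5)
        scene = random_soup_scene(rng, n_tri=30)
        octree = ns.build_octree(scene, max_depth=4, leaf_capacity=4)
        tri_lo = octree.tris.min(axis=1)
        tri_hi = octree.tris.max(axis=1)

        def walk(node):
            if node.is_leaf:
                overlaps = np.nonzero(
                    np.all(tri_lo <= node.hi, axis=1)
                    & np.all(tri_hi >= node.lo, axis=1))[0]
                assert set(overlaps) <= set(node.tri_indices)
            else:
                for c in node.children:
                    walk(c)
        walk(octree.root)

    def test_rebuild_after_deactivation_drops_refs(self, ianb_scene):
        ns.set_structure_active(ianb_scene, "tongue", False)
        octree = ns.build_octree(ianb_scene)
        assert all(name != "tongue" for name, _ in octree.refs)

    def test_empty_scene_rejected(self):
        with pytest.raises(SceneError):
            ns.build_octree(Scene(patient_profile="phantom"))


class TestNearestQuery:
    def test_segment_above_flat_floor(self):
        scene = Scene(patient_profile="phantom")
        verts = np.array([[-5.0, -5, 0], [5, -5, 0], [5, 5, 0], [-5, 5, 0]])
        scene.add_structure(
            TriangleMesh("floor", verts, np.array([[0, 1, 2], [0, 2, 3]])),
            TissueModel("floor", 0.1))
        octree = ns.build_octree(scene)
        seg = ns.NeedleSegment((0.0, 0.0, 1.0), (0.0, 0.0, 3.0))
        res = ns.query_nearest(octree, seg)
        assert res.distance == pytest.approx(1.0, abs=1e-12)
        assert res.structure == "floor"

    def test_intersecting_segment_reports_contact(self, slab_scene):
        octree = ns.build_octree(slab_scene)
        seg = ns.NeedleSegment((0.0, 0.0, 1.0), (0.0, 0.0, -1.0))
        res = ns.query_nearest(octree, seg)
        assert res.distance == 0.0
        assert res.structure == "mucosa"

    def test_matches_brute_force_on_seeded_random_scene(self):
        rng = np.random.default_rng(7)
        scene = random_soup_scene(rng, n_tri=50)
        octree = ns.build_octree(scene, max_depth=6, leaf_capacity=8)
        for _ in range(100):
            seg = random_segment(rng)
            fast = ns.query_nearest(octree, seg)
            slow = ns.brute_force_nearest(scene, seg)
            assert abs(fast.distance - slow.distance) < 1e-9
            if fast.distance > 0:
                assert (fast.structure, fast.face) == (slow.structure,
                                                       slow.face)

    def test_distance_invariant_under_rigid_transform(self):
        rng = np.random.default_rng(21)
        scene = random_soup_scene(rng, n_tri=30)
        seg = random_segment(rng)
        base = ns.brute_force_nearest(scene, seg).distance
        rot = Rotation.random(random_state=11).as_matrix()
        shift = rng.uniform(-50, 50, 3)
        moved = Scene(patient_profile="phantom")
        mesh = scene.structures["soup"].mesh
        moved.add_structure(
            TriangleMesh("soup", mesh.vertices @ rot.T + shift,
                         mesh.faces.copy()),
            TissueModel("soup", 0.1))
        seg2 = ns.NeedleSegment(rot @ seg.tip + shift, rot @ seg.tail + shift)
        assert ns.brute_force_nearest(moved, seg2).distance == pytest.approx(
            base, abs=1e-6)


class TestBruteForce:
    def test_single_triangle_through_centroid(self):
        scene = Scene(patient_profile="phantom")
        verts = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0]])
        scene.add_structure(TriangleMesh("tri", verts, np.array([[0, 1, 2]])),
                            TissueModel("tri", 0.1))
        seg = ns.NeedleSegment((1.0, 1.0, 1.0), (1.0, 1.0, -1.0))
        assert ns.brute_force_nearest(scene, seg).distance == 0.0

    def test_far_segment_distance_lower_bounds_dense_sampling(self):
        rng = np.random.default_rng(13)
        scene = random_soup_scene(rng, n_tri=10, extent=2.0)
        seg = ns.NeedleSegment((20.0, 20.0, 20.0), (25.0, 20.0, 20.0))
        exact = ns.brute_force_nearest(scene, seg).distance
        ts = np.linspace(0, 1, 200)[:, None]
        pts = seg.tip + ts * (seg.tail - seg.tip)
        sampled = min(
            np.linalg.norm(pt - v)
            for pt in pts
            for v in scene.structures["soup"].mesh.vertices)
        assert exact <= sampled + 1e-12
        assert sampled - exact < 0.5

    def test_empty_scene_rejected(self):
        with pytest.raises(SceneError):
            ns.brute_force_nearest(Scene(patient_profile="phantom"),
                                   ns.NeedleSegment((0, 0, 0), (1, 1, 1)))


class TestCrossings:
    def test_full_pass_through_closed_box_enters_and_exits(self, ianb_scene):
        octree = ns.build_octree(ianb_scene)
        crossings = ns.crossings_along_step(
            octree, np.array([0.0, 3.4, 30.0]), np.array([0.0, 3.4, -30.0]))
        mucosa = [c for c in crossings if c.structure == "mucosa"]
        assert [c.kind for c in mucosa] == ["entering", "exiting"]

    def test_zero_length_step_yields_nothing(self, slab_scene):
        octree = ns.build_octree(slab_scene)
        assert ns.crossings_along_step(octree, np.zeros(3), np.zeros(3)) == []

    def test_slab_entering_events_in_layer_order(self, slab_scene):
        octree = ns.build_octree(slab_scene)
        crossings = ns.crossings_along_step(
            octree, np.array([0.0, 0.0, 5.0]), np.array([0.0, 0.0, -25.0]))
        entering = [c.structure for c in crossings if c.kind == "entering"]
        assert entering == ["mucosa", "muscles", "bones"]
        ts = [c.t for c in crossings]
        assert ts == sorted(ts)

    def test_parity_for_watertight_structures(self, ianb_scene):
        rng = np.random.default_rng(3)
        octree = ns.build_octree(ianb_scene)
        for _ in range(25):
            # endpoints far outside the scene bounding box on both sides
            p = np.array([rng.uniform(-40, 40), -50.0, rng.uniform(-40, 40)])
            q = np.array([rng.uniform(-40, 40), 60.0, rng.uniform(-40, 40)])
            counts = {}
            for c in ns.crossings_along_step(octree, p, q):
                delta = 1 if c.kind == "entering" else -1
                counts[c.structure] = counts.get(c.structure, 0) + delta
            assert all(v == 0 for v in counts.values()), counts


def test_segment_triangle_intersection_wrapper():
    seg = ns.NeedleSegment((0.0, 0.0, 1.0), (0.0, 0.0, -1.0))
    tri = np.array([[-1.0, -1, 0], [2, -1, 0], [-1, 2, 0]])
    hit = ns.segment_triangle_intersection(seg, tri)
    np.testing.assert_allclose(hit, [0, 0, 0], atol=1e-12)
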