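"""IANB task checks: angle geometry, entry zone, depth window, nerve contact."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import needlesim as ns
from needlesim.task import (TaskError, check_angle, check_depth,
                            check_entry_point, check_nerve_contact)


class TestInsertionAngle:
    def test_forty_five_degrees(self):
        d = np.array([1.0, 0.0, -1.0]) / np.sqrt(2)
        assert ns.insertion_angle(d, np.array([0.0, 0.0, 1.0])) == \
            pytest.approx(45.0, abs=1e-9)

    def test_in_plane_direction_is_zero(self):
        assert ns.insertion_angle((1.0, 0.0, 0.0), (0.0, 0.0, 1.0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_along_normal_is_ninety(self):
        assert ns.insertion_angle((0.0, 0.0, -1.0), (0.0, 0.0, 1.0)) == \
            pytest.approx(90.0, abs=1e-9)

    def test_zero_direction_rejected(self):
        with pytest.raises(TaskError):
            ns.insertion_angle(np.zeros(3), (0.0, 0.0, 1.0))

    def test_invariant_under_rigid_rotation(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.normal(size=3)
            n = rng.normal(size=3)
            base = ns.insertion_angle(d, n / np.linalg.norm(n))
            rot = Rotation.random(random_state=rng).as_matrix()
            rotated = ns.insertion_angle(rot @ d,
                                         rot @ (n / np.linalg.norm(n)))
            assert rotated == pytest.approx(base, abs=1e-6)


class TestTaskSpec:
    def test_default_target_angle_is_45(self):
        spec = ns.TaskSpec()
        assert spec.target_angle == 45.0

    def test_yaml_roundtrip(self, ianb_scene, tmp_path):
        spec = ns.TaskSpec.for_scene(ianb_scene)
        path = tmp_path / "task.yaml"
        spec.save(path)
        again = ns.TaskSpec.load(path)
        assert again.target_angle == spec.target_angle
        np.testing.assert_allclose(again.entry_center, spec.entry_center)

    def test_invalid_windows_rejected(self):
        with pytest.raises(TaskError):
            ns.TaskSpec(target_angle=120.0)
        with pytest.raises(TaskError):
            ns.TaskSpec(depth_window=(3.0, 0.5))
        with pytest.raises(TaskError):
            ns.TaskSpec(entry_radius=0.0)


class TestIndividualChecks:
    def test_entry_at_center_passes_with_zero_distance(self, ianb_scene):
        spec = ns.TaskSpec.for_scene(ianb_scene)
        res = check_entry_point(spec.entry_center, spec)
        assert res.passed and res.value == 0.0

    def test_entry_just_outside_radius_fails(self, ianb_scene):
        spec = ns.TaskSpec.for_scene(ianb_scene)
        off = spec.entry_center + np.array([spec.entry_radius + 0.1, 0.0,
                                            0.0])
        res = check_entry_point(off, spec)
        assert not res.passed

    def test_no_insertion_message(self):
        res = check_entry_point(None, ns.TaskSpec())
        assert not res.passed
        assert "No insertion" in res.message

    def test_angle_window(self):
        spec = ns.TaskSpec()
        assert check_angle(45.0, spec).passed
        assert check_angle(54.9, spec).passed
        assert not check_angle(25.0, spec).passed

    def test_depth_against_analytic_cylinder_distance(self, ianb_scene):
        spec = ns.TaskSpec.for_scene(ianb_scene)
        r = ianb_scene.metadata["nerve_radius_mm"]
        axis_xy = ianb_scene.landmarks["nerve_base"][:2]
        target = 0.5 * sum(spec.depth_window)
        tip = np.array([axis_xy[0], axis_xy[1] - (r + target), -5.0])
        measured = ns.tip_to_nerve_distance(tip, ianb_scene)
        # the 16-gon nerve cylinder is slightly inside its nominal radius
        assert measured == pytest.approx(target, abs=0.05)
        assert check_depth(tip, ianb_scene, spec).passed

    def test_tip_far_from_nerve_fails_shallow(self, ianb_scene):
        spec = ns.TaskSpec.for_scene(ianb_scene)
        res = check_depth(np.array([0.0, 3.5, -5.0]), ianb_scene, spec)
        assert not res.passed
        assert "shallow" in res.message

    def test_tip_inside_nerve_is_contact_error(self, ianb_scene):
        spec = ns.TaskSpec.for_scene(ianb_scene)
        inside = ianb_scene.landmarks["nerve_base"] + np.array([0, 0, 5.0])
        res = check_depth(inside, ianb_scene, spec)
        assert not res.passed
        assert res.value == 0.0
        assert "nerve" in res.message

    def test_nerve_contact_counting(self):
        spec = ns.TaskSpec()
        assert check_nerve_contact(0, spec).passed
        res = check_nerve_contact(2, spec)
        assert not res.passed and res.value == 2.0


class TestEvaluateSession:
    @pytest.fixture
    def run(self, ianb_scene, calibration):
        def _run(archetype, seed=3, noise=0.0):
            traj = ns.generate_archetype_trajectory(
                ianb_scene, archetype, seed=seed, noise_sd=noise)
            log = ns.run_session(ianb_scene, traj, calibration)
            return ns.evaluate_session(log, ianb_scene,
                                       ns.TaskSpec.for_scene(ianb_scene))
        return _run

    def test_ideal_trajectory_passes_all_checks(self, run):
        result = run("ideal")
        assert result.passed
        assert all(c.passed for c in result.checks.values())
        assert any("deposit the anesthetic" in m for m in result.messages)

    def test_wrong_angle_fails_only_angle(self, run):
        result = run("wrong_angle")
        assert not result.passed
        failed = {k for k, c in result.checks.items() if not c.passed}
        assert failed == {"angle"}
        assert result.checks["angle"].value == pytest.approx(25.0, abs=0.5)

    def test_nerve_hit_records_contact(self, run):
        result = run("nerve_hit")
        assert not result.passed
        assert not result.checks["nerve_contact"].passed
        assert result.checks["nerve_contact"].value >= 1

    def test_shallow_fails_only_depth(self, run):
        result = run("shallow")
        failed = {k for k, c in result.checks.items() if not c.passed}
        assert failed == {"depth"}
        assert "shallow" in result.checks["depth"].message

    def test_replay_yields_identical_result(self, ianb_scene, calibration,
                                            tmp_path):
        traj = ns.generate_archetype_trajectory(ianb_scene, "ideal", seed=5,
                                                noise_sd=0.1)
        log = ns.run_session(ianb_scene, traj, calibration)
        spec = ns.TaskSpec.for_scene(ianb_scene)
        direct = ns.evaluate_session(log, ianb_scene, spec)
        path = tmp_path / "log.jsonl"
        ns.write_log(log, path)
        replayed = ns.evaluate_session(ns.read_log(path), ianb_scene, spec)
        assert replayed == direct

    def test_angle_invariant_under_joint_rotation(self, ianb_scene,
                                                  calibration):
        # rotating scene and trajectory together must not change the angle
        traj = ns.generate_archetype_trajectory(ianb_scene, "ideal", seed=3)
        log = ns.run_session(ianb_scene, traj, calibration)
        spec = ns.TaskSpec.for_scene(ianb_scene)
        base = ns.evaluate_session(log, ianb_scene, spec)

        rot = Rotation.from_euler("xyz", [17.0, -31.0, 45.0],
                                  degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 11.0])
        moved = ns.Scene.from_text(ianb_scene.to_text())
        for s in moved.structures.values():
            s.mesh.vertices = s.mesh.vertices @ rot.T + shift
        moved.occlusal_plane_point = rot @ moved.occlusal_plane_point + shift
        moved.occlusal_plane_normal = rot @ moved.occlusal_plane_normal
        for k in moved.landmarks:
            moved.landmarks[k] = rot @ moved.landmarks[k] + shift
        moved_traj = [
            ns.TrajectorySample(s.t, tuple(rot @ np.array(s.tip) + shift),
                                tuple(rot @ np.array(s.direction)))
            for s in traj]
        moved_log = ns.run_session(moved, moved_traj,
                                   ns.CalibrationTable.from_scene(moved))
        moved_res = ns.evaluate_session(moved_log, moved,
                                        ns.TaskSpec.for_scene(moved))
        assert moved_res.checks["angle"].value == pytest.approx(
            base.checks["angle"].value, abs=1e-6)

    def test_mismatched_scene_refused(self, ianb_scene, calibration):
        traj = ns.generate_archetype_trajectory(ianb_scene, "ideal", seed=3)
        log = ns.run_session(ianb_scene, traj, calibration)
        other = ns.generate_ianb_scene(seed=99)
        with pytest.raises(TaskError, match="recorded against"):
            ns.evaluate_session(log, other, ns.TaskSpec.for_scene(other))
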