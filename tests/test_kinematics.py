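import numpy as np
import pytest

import knee4d as k
from conftest import random_rigid
from knee4d.kinematics import ProjectionDegenerateError

X, Y, Z = np.eye(3)


def frame(bone, T=None):
    f = k.CoordinateFrame(bone, np.zeros(3), X, Y, Z)
    return f if T is None else f.transformed(T)


class TestProjectedAngle:
    def test_reference_axis_gives_zero(self):
        assert k.projected_angle(X, X, Z, X) == pytest.approx(0.0)

    @pytest.mark.parametrize("theta", [10.0, 45.0, 90.0, 135.0, -30.0])
    def test_in_plane_rotation_recovered(self, theta):
        r = np.radians(theta)
        v = np.cos(r) * X + np.sin(r) * Z
        assert k.projected_angle(v, X, Z, X) == pytest.approx(theta)

    def test_out_of_plane_component_ignored(self):
        # the angle depends only on the in-plane part of the vector
        rng = np.random.default_rng(0)
        for _ in range(20):
            theta = rng.uniform(-170, 170)
            r = np.radians(theta)
            v_in = np.cos(r) * X + np.sin(r) * Z
            v = v_in + rng.uniform(-3, 3) * Y
            assert k.projected_angle(v, X, Z, X) == pytest.approx(theta)

    def test_perpendicular_vector_raises(self):
        with pytest.raises(ProjectionDegenerateError):
            k.projected_angle(Y, X, Z, X)

    def test_sign_positive_toward_second_axis(self):
        v = np.cos(0.1) * X + np.sin(0.1) * Z
        mirrored = np.cos(0.1) * X - np.sin(0.1) * Z
        assert k.projected_angle(v, X, Z, X) > 0
        assert k.projected_angle(mirrored, X, Z, X) == pytest.approx(
            -k.projected_angle(v, X, Z, X))


class TestDecompose:
    def test_coincident_frames_all_zero(self):
        pose = k.decompose_ft(frame("femur"), frame("tibia"))
        assert np.allclose(pose.as_vector(), 0.0, atol=1e-12)

    @pytest.mark.parametrize("theta", [10.0, 45.0, 90.0])
    def test_rotation_about_tibial_x_is_pure_flexion(self, theta):
        T = k.RigidTransform.from_rotvec([theta, 0, 0])
        pose = k.decompose_ft(frame("femur", T), frame("tibia"))
        assert pose.flexion_extension_deg == pytest.approx(theta, abs=1e-9)
        assert pose.varus_valgus_deg == pytest.approx(0.0, abs=1e-9)
        assert pose.int_ext_rotation_deg == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 45.0, 90.0])
    def test_rotation_about_tibial_z_is_pure_int_ext(self, theta):
        T = k.RigidTransform.from_rotvec([0, 0, theta])
        pose = k.decompose_ft(frame("femur", T), frame("tibia"))
        assert pose.int_ext_rotation_deg == pytest.approx(theta, abs=1e-9)
        assert pose.flexion_extension_deg == pytest.approx(0.0, abs=1e-9)
        assert pose.varus_valgus_deg == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 45.0, 90.0])
    def test_rotation_about_tibial_y_is_pure_varus(self, theta):
        # femoral X tilts from tibial X toward tibial Z: varus/valgus
        T = k.RigidTransform.from_rotvec([0, -theta, 0])
        pose = k.decompose_ft(frame("femur", T), frame("tibia"))
        assert pose.varus_valgus_deg == pytest.approx(theta, abs=1e-9)
        assert pose.int_ext_rotation_deg == pytest.approx(0.0, abs=1e-9)
        assert pose.flexion_extension_deg == pytest.approx(0.0, abs=1e-9)

    def test_pf_rotation_about_patellar_x_is_pure_flexion(self):
        T = k.RigidTransform.from_rotvec([30.0, 0, 0])
        pose = k.decompose_pf(frame("femur", T), frame("patella"))
        assert pose.flexion_extension_deg == pytest.approx(30.0, abs=1e-9)
        assert pose.varus_valgus_deg == pytest.approx(0.0, abs=1e-9)

    def test_translation_only_gives_offset_in_reference_axes(self):
        T = k.RigidTransform(np.eye(3), [3.0, -4.0, 5.0])
        ref = frame("patella",
                    k.RigidTransform.from_rotvec([0, 0, 90.0]))
        pose = k.decompose_pf(frame("femur", T), ref)
        # reference rotated 90 deg about Z: x_local = global y etc.
        assert np.allclose(pose.position_mm, [-4.0, -3.0, 5.0], atol=1e-9)
        assert pose.flexion_extension_deg == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_projection_zero_by_continuity_or_strict_error(self):
        # femoral X along tibial Y: varus projection undefined; default
        # continuity convention returns 0, strict mode reports it
        T = k.RigidTransform.from_rotvec([0, 0, 90.0])
        pose = k.decompose_ft(frame("femur", T), frame("tibia"))
        assert pose.varus_valgus_deg == 0.0
        assert pose.int_ext_rotation_deg == pytest.approx(90.0, abs=1e-9)
        with pytest.raises(ProjectionDegenerateError, match="varus"):
            k.decompose_ft(frame("femur", T), frame("tibia"), strict=True)

    def test_invariance_under_common_global_motion(self):
        rng = np.random.default_rng(5)
        Tf = random_rigid(rng, max_angle_deg=40)
        Tt = random_rigid(rng, max_angle_deg=40)
        base = k.decompose_ft(frame("femur", Tf), frame("tibia", Tt))
        for _ in range(20):
            G = random_rigid(rng)
            moved = k.decompose_ft(frame("femur", G.compose(Tf)),
                                   frame("tibia", G.compose(Tt)))
            assert np.abs(moved.as_vector() - base.as_vector()).max() < 1e-8

    def test_projected_angles_differ_from_euler_for_combined_rotations(self):
        # the projected-angle convention is NOT a cardan sequence: for a
        # combined rotation at least one component must disagree with the
        # xyz-Euler decomposition of the same relative rotation
        from scipy.spatial.transform import Rotation
        T = k.RigidTransform.from_rotvec([40.0, 25.0, 30.0])
        pose = k.decompose_ft(frame("femur", T), frame("tibia"))
        eul = Rotation.from_matrix(T.rotation).as_euler("xyz", degrees=True)
        ours = np.array([pose.flexion_extension_deg, pose.varus_valgus_deg,
                         pose.int_ext_rotation_deg])
        assert np.abs(ours - np.array([eul[0], -eul[1], eul[2]])).max() > 0.5


class TestSeries:
    def test_ground_truth_track_reproduces_commanded_flexion(
            self, static_frames, script):
        series = k.series_from_tracks(static_frames,
                                      script.ground_truth_tracks())
        fe = series["FT"].as_matrix()[:, 5]
        commanded = np.array([script.flexion_angle_deg(t)
                              for t in script.volume_times()])
        assert np.abs(fe - commanded).max() < 1e-6
        # and the sweep really goes up, down and up again
        assert fe.max() > 85 and fe[9:16].min() < 5 and fe[-1] > 30

    def test_identity_track_gives_static_offsets_and_zero_angles(
            self, static_frames, script):
        times = script.volume_times()
        ident = {b: k.PoseTrack(b, times,
                                [k.RigidTransform.identity()] * len(times),
                                "ground_truth") for b in k.BONES}
        series = k.series_from_tracks(static_frames, ident)
        for joint in k.JOINTS:
            m = series[joint].as_matrix()
            assert np.allclose(m[:, 3:], 0.0, atol=1e-9)
            assert np.allclose(m, m[0], atol=1e-12)   # constant over time

    def test_registered_track_matches_ground_truth_series(self, phantom,
                                                          static_frames):
        script = k.make_motion_script(n_volumes=6, max_flexion_deg=30,
                                      final_flexion_deg=15)
        dyn = k.sample_dynamic_meshes(phantom.meshes, script,
                                      k.ArtifactParams(0, 0, 0, 0))
        reg, _ = k.register_sequence(phantom.meshes, dyn,
                                     k.ICPParams(seed=8),
                                     timestamps=script.volume_times())
        a = k.series_from_tracks(static_frames, reg)
        b = k.series_from_tracks(static_frames, script.ground_truth_tracks())
        for joint in k.JOINTS:
            assert np.abs(a[joint].as_matrix()
                          - b[joint].as_matrix()).max() < 1e-3

    def test_timestamp_mismatch_rejected(self, static_frames, script):
        tracks = script.ground_truth_tracks()
        bad = k.PoseTrack("tibia", tracks["tibia"].timestamps + 1.0,
                          tracks["tibia"].transforms, "ground_truth")
        tracks["tibia"] = bad
        with pytest.raises(ValueError):
            k.series_from_tracks(static_frames, tracks)


def test_kinematics_csv_roundtrip(tmp_path, static_frames, script):
    series = k.series_from_tracks(static_frames, script.ground_truth_tracks())
    p = tmp_path / "kin.csv"
    k.save_kinematics(series, p)
    import pandas as pd
    df = pd.read_csv(p)
    assert set(df.joint) == set(k.JOINTS)
    assert len(df) == 2 * script.n_volumes
    assert list(df.columns[:2]) == ["t_s", "joint"]
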