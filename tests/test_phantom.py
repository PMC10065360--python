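import numpy as np
import pytest

import knee4d as k


# ---------------------------------------------------------------------- #
# bone generation
# ---------------------------------------------------------------------- #

class TestGenerateBoneMesh:
    def test_femur_hip_center_along_shaft(self):
        mesh, lm = k.generate_bone_mesh("femur", seed=1)
        shaft = lm["hip_center"] - lm["canal_distal_exit"]
        assert np.linalg.norm(shaft) == pytest.approx(400.0)
        assert np.allclose(shaft / np.linalg.norm(shaft), [0, 0, 1])

    def test_patella_base_apex_height(self):
        mesh, lm = k.generate_bone_mesh("patella", seed=1)
        assert np.linalg.norm(lm["base"] - lm["apex"]) == pytest.approx(40.0)

    @pytest.mark.parametrize("bone", k.BONES)
    def test_same_seed_is_byte_identical(self, bone):
        m1, lm1 = k.generate_bone_mesh(bone, seed=3)
        m2, lm2 = k.generate_bone_mesh(bone, seed=3)
        assert np.array_equal(m1.vertices, m2.vertices)
        assert np.array_equal(m1.faces, m2.faces)
        for name in lm1.points:
            assert np.array_equal(lm1[name], lm2[name])

    def test_required_landmarks_present(self):
        for bone in k.BONES:
            _, lm = k.generate_bone_mesh(bone, seed=0)
            lm.require(*__import__("knee4d").meshes.REQUIRED_LANDMARKS[bone])

    def test_unknown_bone_rejected(self):
        with pytest.raises(ValueError):
            k.generate_bone_mesh("fibula", seed=0)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            k.generate_bone_mesh("femur", k.ShapeParams(femur_length=-1),
                                 seed=0)


# ---------------------------------------------------------------------- #
# motion script
# ---------------------------------------------------------------------- #

class TestMotionScript:
    def test_default_20_volumes_identity_at_t0(self, script):
        assert script.n_volumes == 20
        assert len(script.volume_times()) == 20
        for bone in k.BONES:
            assert script.pose(bone, 0.0).almost_equal(
                k.RigidTransform.identity())

    def test_flexion_profile_flex_extend_flex(self, script):
        # 0 -> 90 -> 0 -> partial, within [0, 90] throughout
        t = np.linspace(0, script.duration_s, 400)
        ang = np.array([script.flexion_angle_deg(x) for x in t])
        assert ang.min() >= -1e-9 and ang.max() <= 90 + 1e-9
        assert script.flexion_angle_deg(0.0) == pytest.approx(0.0)
        # peak flexion is reached at the end of the first segment
        assert script.flexion_angle_deg(
            0.4 * script.duration_s) == pytest.approx(90.0)
        # extension returns to 0 at the end of the second segment
        assert script.flexion_angle_deg(
            0.8 * script.duration_s) == pytest.approx(0.0, abs=1e-9)
        assert script.flexion_angle_deg(script.duration_s) == pytest.approx(
            script.final_flexion_deg)

    def test_two_volume_script(self):
        s = k.make_motion_script(10.5, 2, 90)
        assert len(s.volume_times()) == 2

    def test_femur_fixed_at_all_times(self, script):
        for t in script.volume_times():
            assert script.pose("femur", t).almost_equal(
                k.RigidTransform.identity())

    def test_peak_tibia_pose_decomposes_to_90_flexion(self, static_frames):
        # closed-form oracle: tibia rotated to peak flexion must decompose
        # back to the commanded 90 degrees
        script = k.make_motion_script()
        t_peak = 0.4 * script.duration_s   # end of the flexion segment
        assert script.flexion_angle_deg(t_peak) == pytest.approx(90.0)
        femur = static_frames["femur"].transformed(script.pose("femur", t_peak))
        tibia = static_frames["tibia"].transformed(script.pose("tibia", t_peak))
        pose = k.decompose_ft(femur, tibia)
        assert pose.flexion_extension_deg == pytest.approx(90.0, abs=1e-9)

    def test_flexion_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            k.make_motion_script(10.5, 20, 150.0)
        with pytest.raises(ValueError):
            k.MotionScript(duration_s=-1.0)


# ---------------------------------------------------------------------- #
# dynamic meshes / artifacts
# ---------------------------------------------------------------------- #

class TestDynamicMeshes:
    def test_zero_artifacts_exact_rigid_copies(self, phantom, script):
        dyn = k.sample_dynamic_meshes(phantom.meshes, script,
                                      k.ArtifactParams(0, 0, 0, 0))
        assert len(dyn) == script.n_volumes
        for kk, t in enumerate(script.volume_times()):
            for bone, mesh in phantom.meshes.items():
                exact = script.pose(bone, t).apply(mesh.vertices)
                assert np.array_equal(dyn[kk][bone].vertices, exact)
                assert np.array_equal(dyn[kk][bone].faces, mesh.faces)

    def test_near_zero_velocity_volume_jitter_only(self, phantom):
        # a motion extreme: corruption magnitude approximately the jitter
        # baseline (mean |N(0, s I3)| = 2 sqrt(2/pi) s)
        script = k.make_motion_script()
        params = k.ArtifactParams(jitter_sigma_mm=0.3,
                                  smear_gain_mm_per_mm_s=0.005,
                                  dropout_fraction=0.0, seed=9)
        corr = k.corruption_per_volume(phantom.meshes, script, params)
        expected_baseline = 0.3 * 2 * np.sqrt(2 / np.pi)
        # volumes 0 and 7/8 sit at velocity minima of the profile
        assert corr[0] == pytest.approx(expected_baseline, rel=0.05)

    def test_corruption_peaks_at_high_speed_volumes(self, phantom, script):
        params = k.ArtifactParams(seed=5)
        corr = k.corruption_per_volume(phantom.meshes, script, params)
        speeds = np.array([
            np.mean([np.linalg.norm(
                k.vertex_velocities(m, script, t), axis=1).mean()
                for m in phantom.meshes.values()])
            for t in script.volume_times()])
        fast = set(np.flatnonzero(speeds >= 0.99 * speeds.max()))
        assert int(corr.argmax()) in fast
        assert corr[list(fast)].min() > corr[speeds.argmin()]

    def test_dropout_removes_faces_and_vertices(self, phantom, script):
        dyn = k.sample_dynamic_meshes(
            phantom.meshes, script,
            k.ArtifactParams(0.1, 0.0, dropout_fraction=0.2, seed=2))
        for bone, mesh in phantom.meshes.items():
            assert len(dyn[0][bone].faces) < len(mesh.faces)
            assert len(dyn[0][bone].vertices) <= len(mesh.vertices)

    def test_invalid_artifact_params_rejected(self):
        with pytest.raises(ValueError):
            k.ArtifactParams(jitter_sigma_mm=-0.1)
        with pytest.raises(ValueError):
            k.ArtifactParams(dropout_fraction=0.6)


# ---------------------------------------------------------------------- #
# mocap reference
# ---------------------------------------------------------------------- #

class TestMocap:
    def test_zero_noise_equals_ground_truth(self, script):
        tracks = k.simulate_mocap_track(script, 0.0, 0.0, seed=11)
        gt = script.ground_truth_tracks()
        for bone in k.BONES:
            dt, dr = tracks[bone].max_difference(gt[bone])
            assert dt < 1e-12 and dr < 1e-12

    def test_same_seed_identical(self, script):
        a = k.simulate_mocap_track(script, 0.6, 1.0, seed=7)
        b = k.simulate_mocap_track(script, 0.6, 1.0, seed=7)
        for bone in k.BONES:
            for Ta, Tb in zip(a[bone].transforms, b[bone].transforms):
                assert np.array_equal(Ta.as_flat_row(), Tb.as_flat_row())

    def test_translation_error_calibration(self):
        # Monte-Carlo over >= 1000 samples: mean pose translation error
        # matches the nominal 0.6 mm within 10%
        script = k.MotionScript(n_volumes=340)
        tracks = k.simulate_mocap_track(script, 0.6, 1.0, seed=13)
        gt = script.ground_truth_tracks()
        errs = [a.difference(b)[0]
                for bone in k.BONES
                for a, b in zip(gt[bone].transforms, tracks[bone].transforms)]
        assert np.mean(errs) == pytest.approx(0.6, rel=0.10)

    def test_rotation_error_bounded(self, script):
        tracks = k.simulate_mocap_track(script, 0.6, 1.0, seed=17)
        gt = script.ground_truth_tracks()
        for bone in k.BONES:
            for a, b in zip(gt[bone].transforms, tracks[bone].transforms):
                assert a.difference(b)[1] <= 1.0 + 1e-9

    def test_negative_error_rejected(self, script):
        with pytest.raises(ValueError):
            k.simulate_mocap_track(script, -0.1, 1.0, seed=0)
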