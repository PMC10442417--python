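"""Monocular lifting: energy, initialization, optimization, sequences."""

import numpy as np
import pytest

import mouselift as ml
from mouselift.optimize import TooFewKeypointsError
from mouselift.synthetic import render_scene, sample_pose


def make_scene(skeleton, camera, seed, noise=0.0, occlusion=0.0,
               phase=None):
    rng = np.random.default_rng(seed)
    pose = sample_pose(skeleton, "gait", phase=phase,
                       seed=int(rng.integers(2 ** 31)))
    pose.angles[3 * skeleton.root_index + 2] = rng.uniform(-np.pi, np.pi)
    pose.root_translation = np.array(
        [rng.uniform(-20, 20), rng.uniform(-20, 20), 30.0])
    scene = render_scene(skeleton, pose, [camera], noise, occlusion,
                         seed=int(rng.integers(2 ** 31)))
    distance = float(np.linalg.norm(pose.root_translation - camera.center))
    return scene, distance


def joint_errors(skeleton, fit_pose, scene):
    kp = ml.forward_kinematics(skeleton, fit_pose)
    n = skeleton.n_joints
    return np.linalg.norm(
        kp.positions[:n] - scene.true_keypoints.positions[:n], axis=1)


class TestEnergy:
    def test_zero_residual_at_exact_observations(self, skeleton, top_camera):
        scene, d = make_scene(skeleton, top_camera, seed=0)
        cfg = ml.EnergyConfig(fixed_distance=d, lambda_pose=0.0,
                              lambda_shape=0.0)
        total, br = ml.energy(scene.true_pose, scene.observations[0],
                              top_camera, skeleton, None, None, cfg)
        assert total == pytest.approx(0.0, abs=1e-12)
        assert br.reprojection == pytest.approx(0.0, abs=1e-12)

    def test_three_four_five_offset(self, skeleton, top_camera):
        scene, d = make_scene(skeleton, top_camera, seed=1)
        obs = scene.observations[0]
        idx = obs.names.index("nose")
        obs.uv[idx] += [3.0, 4.0]
        cfg = ml.EnergyConfig(fixed_distance=d, lambda_pose=0.0,
                              lambda_shape=0.0)
        total, _ = ml.energy(scene.true_pose, obs, top_camera, skeleton,
                             None, None, cfg)
        assert total == pytest.approx(25.0, abs=1e-9)

    def test_additive_decomposition(self, skeleton, top_camera, pose_prior,
                                    shape_prior):
        scene, d = make_scene(skeleton, top_camera, seed=2)
        cfg = ml.EnergyConfig(fixed_distance=d, lambda_pose=1.0,
                              lambda_shape=0.7)
        total, br = ml.energy(scene.true_pose, scene.observations[0],
                              top_camera, skeleton, pose_prior, shape_prior,
                              cfg)
        assert total == pytest.approx(
            br.reprojection + 1.0 * br.pose_nll + 0.7 * br.shape_nll,
            abs=1e-9)
        # pose_nll term equals the prior NLL of the normalized FK pose
        kp = ml.forward_kinematics(skeleton, scene.true_pose)
        feats = ml.normalize_pose(kp, skeleton.joint_names).flatten()
        assert br.pose_nll == pytest.approx(
            ml.neg_log_likelihood(pose_prior, feats), abs=1e-9)

    def test_all_keypoints_excluded_is_an_error(self, skeleton, top_camera):
        scene, d = make_scene(skeleton, top_camera, seed=3)
        obs = scene.observations[0]
        obs.confidence[:] = 0.0
        cfg = ml.EnergyConfig(fixed_distance=d)
        with pytest.raises(TooFewKeypointsError):
            ml.energy(scene.true_pose, obs, top_camera, skeleton, None,
                      None, cfg)


class TestInitializePose:
    def test_spine_reprojection_close_for_rest_pose(self, skeleton,
                                                    top_camera, shape_prior):
        pose = skeleton.rest_pose(root_translation=(5.0, -3.0, 30.0))
        scene = render_scene(skeleton, pose, [top_camera], 0.0, 0.0, seed=0)
        d = float(np.linalg.norm(pose.root_translation - top_camera.center))
        cfg = ml.EnergyConfig(fixed_distance=d)
        init = ml.initialize_pose(scene.observations[0], top_camera,
                                  skeleton, cfg, shape_prior)
        kp = ml.forward_kinematics(skeleton, init)
        from mouselift.geometry import project
        errs = []
        for name in ("lower_spine", "middle_spine", "upper_spine"):
            uv = project(top_camera, kp.get(name))
            errs.append(np.linalg.norm(uv - scene.observations[0].get(name)))
        assert np.sqrt(np.mean(np.square(errs))) < 5.0

    def test_in_plane_rotation_rotates_yaw(self, skeleton, top_camera):
        pose = skeleton.rest_pose(root_translation=(0.0, 0.0, 30.0))
        scene = render_scene(skeleton, pose, [top_camera], 0.0, 0.0, seed=0)
        obs = scene.observations[0]
        d = float(np.linalg.norm(pose.root_translation - top_camera.center))
        cfg = ml.EnergyConfig(fixed_distance=d)
        _, info0 = ml.initialize_pose(obs, top_camera, skeleton, cfg,
                                      with_info=True)
        center = np.array([top_camera.cx, top_camera.cy])
        rot90 = np.array([[0.0, -1.0], [1.0, 0.0]])
        rotated = ml.ObservedKeypoints2D(
            names=obs.names, uv=(obs.uv - center) @ rot90.T + center,
            confidence=obs.confidence)
        _, info1 = ml.initialize_pose(rotated, top_camera, skeleton, cfg,
                                      with_info=True)
        delta = (info1["yaw"] - info0["yaw"] + np.pi) % (2 * np.pi) - np.pi
        assert abs(abs(delta) - np.pi / 2) < 1e-6

    def test_zero_confidence_takes_fallback(self, skeleton, top_camera):
        pose = skeleton.rest_pose(root_translation=(0.0, 0.0, 30.0))
        scene = render_scene(skeleton, pose, [top_camera], 0.0, 0.0, seed=0)
        obs = scene.observations[0]
        obs.confidence[:] = 0.0
        cfg = ml.EnergyConfig(fixed_distance=370.0)
        init, info = ml.initialize_pose(obs, top_camera, skeleton, cfg,
                                        with_info=True)
        assert info["used_fallback"]
        assert np.all(np.isfinite(init.root_translation))


class TestOptimizePose:
    def test_truth_is_a_fixed_point_without_priors(self, skeleton,
                                                   top_camera):
        scene, d = make_scene(skeleton, top_camera, seed=4)
        cfg = ml.EnergyConfig(fixed_distance=d, lambda_pose=0.0,
                              lambda_shape=0.0)
        fit = ml.optimize_pose(scene.observations[0], top_camera, skeleton,
                               None, None, cfg, initial=scene.true_pose)
        assert fit.final_reprojection_rmse < 1e-6
        errs = joint_errors(skeleton, fit.pose, scene)
        assert errs.max() < 1e-3

    def test_noiseless_recovery_small_harness(self, skeleton, top_camera,
                                              pose_prior, shape_prior):
        errs = []
        for seed in range(6):
            scene, d = make_scene(skeleton, top_camera, seed=100 + seed)
            cfg = ml.EnergyConfig(fixed_distance=d)
            fit = ml.optimize_pose(scene.observations[0], top_camera,
                                   skeleton, pose_prior, shape_prior, cfg)
            assert fit.converged
            errs.append(joint_errors(skeleton, fit.pose, scene))
        assert np.median(np.concatenate(errs)) < 1.0

    def test_energy_trace_monotone_and_consistent(self, skeleton, top_camera,
                                                  pose_prior, shape_prior):
        scene, d = make_scene(skeleton, top_camera, seed=5)
        cfg = ml.EnergyConfig(fixed_distance=d)
        fit = ml.optimize_pose(scene.observations[0], top_camera, skeleton,
                               pose_prior, shape_prior, cfg)
        assert np.all(np.diff(fit.energy_trace) <= 1e-9)
        assert fit.final_energy == pytest.approx(fit.breakdown.total,
                                                 abs=1e-9)
        # final energy never exceeds the initial energy
        assert fit.final_energy <= fit.energy_trace[0] + 1e-9

    def test_too_few_keypoints_raises(self, skeleton, top_camera):
        scene, d = make_scene(skeleton, top_camera, seed=6)
        obs = scene.observations[0]
        obs.confidence[:] = 0.0
        obs.confidence[:3] = 1.0
        cfg = ml.EnergyConfig(fixed_distance=d)
        with pytest.raises(TooFewKeypointsError):
            ml.optimize_pose(obs, top_camera, skeleton, None, None, cfg)

    def test_root_stays_on_fixed_distance_sphere(self, skeleton, top_camera,
                                                 pose_prior, shape_prior):
        scene, d = make_scene(skeleton, top_camera, seed=7, noise=1.0)
        cfg = ml.EnergyConfig(fixed_distance=d)
        fit = ml.optimize_pose(scene.observations[0], top_camera, skeleton,
                               pose_prior, shape_prior, cfg)
        dist = np.linalg.norm(fit.pose.root_translation - top_camera.center)
        assert dist == pytest.approx(d, abs=1e-9)

    def test_recovery_degrades_smoothly_with_wrong_distance(
            self, skeleton, top_camera, pose_prior, shape_prior):
        """Scale identifiability: misconfiguring the fixed distance by up to
        +-10% shifts the recovered pose smoothly, without divergence."""
        scene, d = make_scene(skeleton, top_camera, seed=8)
        meds = []
        for factor in (0.9, 1.0, 1.1):
            cfg = ml.EnergyConfig(fixed_distance=d * factor)
            fit = ml.optimize_pose(scene.observations[0], top_camera,
                                   skeleton, pose_prior, shape_prior, cfg)
            meds.append(np.median(joint_errors(skeleton, fit.pose, scene)))
        assert meds[1] == min(meds)
        assert max(meds) < 0.2 * d  # bounded, no divergence
        # error grows roughly with the distance offset (~37 mm here)
        assert meds[0] > meds[1] and meds[2] > meds[1]


class TestLiftSequence:
    def test_constant_pose_warm_start_fixed_point(self, skeleton, top_camera,
                                                  pose_prior, shape_prior):
        scene, d = make_scene(skeleton, top_camera, seed=9)
        frames = [scene.observations[0]] * 5
        cfg = ml.EnergyConfig(fixed_distance=d)
        fits = ml.lift_sequence(frames, top_camera, skeleton, pose_prior,
                                shape_prior, cfg)
        ref = ml.forward_kinematics(skeleton, fits[1].pose).positions
        for fit in fits[2:]:
            kp = ml.forward_kinematics(skeleton, fit.pose).positions
            # identical to solver-tolerance wander (well below a micron)
            assert np.allclose(kp, ref, atol=1e-3)

    def test_failed_frame_is_flagged_and_sequence_recovers(
            self, skeleton, top_camera, pose_prior, shape_prior):
        scene, d = make_scene(skeleton, top_camera, seed=10)
        good = scene.observations[0]
        bad = ml.ObservedKeypoints2D(names=good.names, uv=good.uv.copy(),
                                     confidence=np.zeros(len(good.names)))
        cfg = ml.EnergyConfig(fixed_distance=d)
        fits = ml.lift_sequence([good, bad, good], top_camera, skeleton,
                                pose_prior, shape_prior, cfg)
        assert fits[0].pose is not None
        assert fits[1].pose is None and fits[1].error
        assert fits[2].pose is not None and fits[2].converged

    def test_empty_sequence_rejected(self, skeleton, top_camera):
        cfg = ml.EnergyConfig(fixed_distance=370.0)
        with pytest.raises(ValueError):
            ml.lift_sequence([], top_camera, skeleton, None, None, cfg)
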