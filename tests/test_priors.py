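"""Pose normalization and Gaussian-mixture priors."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import mouselift as ml
from mouselift.priors import DegeneratePoseError, neg_log_likelihood
from mouselift.synthetic import (sample_cohort_bone_lengths, sample_pose,
                                 sample_pose_collection)


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.from_rotvec(rng.uniform(-np.pi, np.pi, 3)).as_matrix()
    t = rng.uniform(-100, 100, 3)
    s = rng.uniform(0.3, 3.0)
    return R, t, s


class TestNormalizePose:
    def test_canonical_pose_unchanged(self, skeleton):
        kp = ml.forward_kinematics(skeleton, skeleton.rest_pose())
        n1 = ml.normalize_pose(kp, skeleton.joint_names)
        # renormalizing the normalized coordinates is the identity
        kp2 = ml.Keypoints3D(n1.names, n1.coordinates)
        n2 = ml.normalize_pose(kp2, skeleton.joint_names)
        assert np.allclose(n2.coordinates, n1.coordinates, atol=1e-9)

    def test_pins_spine_reference_frame(self, skeleton):
        pose = sample_pose(skeleton, "gait", phase=0.7, seed=3)
        kp = ml.forward_kinematics(skeleton, pose)
        norm = ml.normalize_pose(kp, skeleton.joint_names)
        us = norm.coordinates[norm.names.index("upper_spine")]
        msp = norm.coordinates[norm.names.index("middle_spine")]
        assert np.allclose(us, 0.0, atol=1e-9)
        assert np.allclose(msp, [1.0, 0.0, 0.0], atol=1e-9)
        hips = 0.5 * (norm.coordinates[norm.names.index("left_hip")]
                      + norm.coordinates[norm.names.index("right_hip")])
        assert abs(hips[1]) < 1e-9
        assert hips[2] < 0  # ventral side down

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_invariant_to_rigid_motion_and_scale(self, skeleton, seed):
        pose = sample_pose(skeleton, "gait", seed=seed)
        kp = ml.forward_kinematics(skeleton, pose)
        base = ml.normalize_pose(kp, skeleton.joint_names)
        R, t, s = random_rigid(seed + 100)
        moved = ml.Keypoints3D(kp.names, s * kp.positions @ R.T + t)
        out = ml.normalize_pose(moved, skeleton.joint_names)
        assert np.allclose(out.coordinates, base.coordinates, atol=1e-9)

    def test_coincident_spine_points_rejected(self, skeleton):
        kp = ml.forward_kinematics(skeleton, skeleton.rest_pose())
        pts = kp.positions.copy()
        i = kp.names.index("middle_spine")
        pts[i] = kp.get("upper_spine")
        with pytest.raises(DegeneratePoseError):
            ml.normalize_pose(ml.Keypoints3D(kp.names, pts),
                              skeleton.joint_names)


class TestFitGmm:
    def test_single_gaussian_recovery(self):
        rng = np.random.default_rng(0)
        mean = np.array([2.0, -1.0])
        cov = np.array([[1.0, 0.3], [0.3, 0.5]])
        X = rng.multivariate_normal(mean, cov, size=500)
        prior = ml.fit_gmm(X, n_components=1, seed=0)
        se = np.sqrt(np.diag(cov) / 500)
        assert np.all(np.abs(prior.means[0] - mean) < 3 * se)
        rel = np.linalg.norm(prior.covariances[0] - cov) / np.linalg.norm(cov)
        assert rel < 0.2

    def test_two_separated_clusters(self):
        rng = np.random.default_rng(1)
        X = np.concatenate([rng.normal(0.0, 0.05, (200, 3)),
                            rng.normal(5.0, 0.05, (200, 3))])
        prior = ml.fit_gmm(X, n_components=2, seed=1)
        centers = np.sort(prior.means[:, 0])
        assert abs(centers[0] - 0.0) < 0.1
        assert abs(centers[1] - 5.0) < 0.1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            ml.fit_gmm(np.zeros((3, 2)), n_components=5, seed=0)

    def test_zero_variance_dimension_floored_with_warning(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(0, 1, 100), np.full(100, 7.0)])
        with pytest.warns(UserWarning):
            prior = ml.fit_gmm(X, n_components=1, seed=0)
        assert np.linalg.eigvalsh(prior.covariances[0]).min() > 0

    def test_fixed_seed_is_reproducible(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (120, 4))
        p1 = ml.fit_gmm(X, n_components=3, seed=9)
        p2 = ml.fit_gmm(X, n_components=3, seed=9)
        assert np.array_equal(p1.weights, p2.weights)
        assert np.array_equal(p1.means, p2.means)
        assert np.array_equal(p1.covariances, p2.covariances)


class TestNegLogLikelihood:
    def test_standard_normal_closed_form(self):
        prior = ml.GmmPrior(weights=[1.0], means=[[0.0]],
                            covariances=[[[1.0]]])
        val = neg_log_likelihood(prior, np.array([0.0]))
        assert val == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_minimum_at_single_component_mean(self):
        prior = ml.GmmPrior(weights=[1.0], means=[[1.0, -2.0]],
                            covariances=[np.diag([0.5, 2.0])])
        at_mean = neg_log_likelihood(prior, np.array([1.0, -2.0]))
        rng = np.random.default_rng(0)
        for _ in range(50):
            delta = rng.normal(0, 1, 2)
            assert neg_log_likelihood(
                prior, np.array([1.0, -2.0]) + delta) >= at_mean

    def test_symmetric_mixture_equal_at_both_means(self):
        prior = ml.GmmPrior(weights=[0.5, 0.5], means=[[-3.0], [3.0]],
                            covariances=[[[1.0]], [[1.0]]])
        a = neg_log_likelihood(prior, np.array([-3.0]))
        b = neg_log_likelihood(prior, np.array([3.0]))
        assert a == pytest.approx(b, abs=1e-12)

    def test_dimension_mismatch_rejected(self):
        prior = ml.GmmPrior(weights=[1.0], means=[[0.0, 0.0]],
                            covariances=[np.eye(2)])
        with pytest.raises(ValueError):
            neg_log_likelihood(prior, np.zeros(3))

    def test_bounded_below_by_peak_density(self, shape_prior):
        rng = np.random.default_rng(4)
        floor = shape_prior.nll_lower_bound()
        X = rng.uniform(1, 40, (200, shape_prior.dimension))
        assert np.all(neg_log_likelihood(shape_prior, X) >= floor - 1e-9)


class TestPosePrior:
    def test_in_distribution_poses_score_better_than_random(
            self, skeleton, pose_prior):
        rng = np.random.default_rng(5)
        wins = 0
        for trial in range(30):
            gait = sample_pose(skeleton, "gait",
                               seed=int(rng.integers(2 ** 31)))
            rand = sample_pose(skeleton, "random",
                               seed=int(rng.integers(2 ** 31)))
            rand.bone_lengths = gait.bone_lengths.copy()
            nll_g = neg_log_likelihood(pose_prior, ml.normalize_pose(
                ml.forward_kinematics(skeleton, gait),
                skeleton.joint_names).flatten())
            nll_r = neg_log_likelihood(pose_prior, ml.normalize_pose(
                ml.forward_kinematics(skeleton, rand),
                skeleton.joint_names).flatten())
            wins += nll_g < nll_r
        assert wins == 30

    def test_prior_invariant_to_rigid_motion_of_training_poses(
            self, skeleton):
        poses = sample_pose_collection(skeleton, 40, seed=11)
        R, t, s = random_rigid(77)
        moved = [ml.Keypoints3D(p.names, s * p.positions @ R.T + t)
                 for p in poses]
        p1 = ml.fit_pose_prior(poses, seed=5)
        p2 = ml.fit_pose_prior(moved, seed=5)
        assert np.allclose(p1.means, p2.means, atol=1e-6)
        assert np.allclose(p1.weights, p2.weights, atol=1e-9)

    def test_too_few_poses_rejected(self, skeleton):
        poses = sample_pose_collection(skeleton, 4, seed=0)
        with pytest.raises(ValueError):
            ml.fit_pose_prior(poses, seed=0)

    def test_five_components(self, pose_prior):
        assert pose_prior.n_components == 5
        assert pose_prior.dimension == 54


class TestShapePrior:
    def test_seven_components_on_cohort(self, shape_prior):
        assert shape_prior.n_components == 7
        assert shape_prior.dimension == 17

    def test_group_means_score_better_than_doubled_lengths(
            self, cohort_table, shape_prior, skeleton):
        bones = list(skeleton.bone_names)
        for g, block in cohort_table.groupby("group"):
            mean = block[bones].to_numpy().mean(axis=0)
            assert (neg_log_likelihood(shape_prior, mean)
                    < neg_log_likelihood(shape_prior, 2 * mean))

    def test_specimen_order_irrelevant(self, cohort_table, skeleton):
        bones = list(skeleton.bone_names)
        X = cohort_table[bones].to_numpy()
        p1 = ml.fit_shape_prior(X, seed=8)
        perm = np.random.default_rng(0).permutation(len(X))
        p2 = ml.fit_shape_prior(X[perm], seed=8)
        order1 = np.argsort(p1.means[:, 0])
        order2 = np.argsort(p2.means[:, 0])
        assert np.allclose(p1.means[order1], p2.means[order2], atol=1e-6)

    def test_negative_length_rejected(self):
        X = np.abs(np.random.default_rng(0).normal(20, 2, (10, 17)))
        X[3, 5] = -1.0
        with pytest.raises(ValueError):
            ml.fit_shape_prior(X, seed=0, n_components=2)


class TestPriorIO:
    def test_save_load_roundtrip(self, shape_prior, tmp_path):
        path = tmp_path / "prior.json"
        ml.save_prior(shape_prior, path)
        loaded = ml.load_prior(path)
        assert np.allclose(loaded.weights, shape_prior.weights)
        assert np.allclose(loaded.means, shape_prior.means)
        assert np.allclose(loaded.covariances, shape_prior.covariances)
        assert loaded.kind == shape_prior.kind
        assert loaded.feature_names == shape_prior.feature_names
        x = shape_prior.means[0]
        assert neg_log_likelihood(loaded, x) == pytest.approx(
            neg_log_likelihood(shape_prior, x), rel=1e-12)
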