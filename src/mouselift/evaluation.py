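"""Self-contained recovery benchmarks on synthetic ground truth.

These harnesses quantify, end to end, how well each reconstruction stage
recovers known synthetic truth: single-view lifting accuracy under noise
and occlusion, multiview triangulation accuracy, and prior quality
(cluster recovery for the shape prior, likelihood ranking for the pose
prior).  Every harness is a pure function of its parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import CameraModel
from .optimize import EnergyConfig, optimize_pose
from .priors import (fit_pose_prior, fit_shape_prior, neg_log_likelihood,
                     normalize_pose)
from .skeleton import SkeletonDefinition, forward_kinematics
from .synthetic import (default_rig, render_scene,
                        sample_cohort_bone_lengths, sample_pose,
                        sample_pose_collection)

__all__ = [
    "RecoveryResult",
    "build_default_priors",
    "single_view_recovery",
    "multiview_recovery",
    "shape_prior_cluster_recovery",
    "pose_prior_ranking",
]

N_POSE_PRIOR_TRAINING = 200
N_COHORT_SPECIMENS = 80
N_COHORT_GROUPS = 4


@dataclass
class RecoveryResult:
    per_joint_errors_mm: np.ndarray   # pooled over scenes and joints
    per_scene_median_mm: np.ndarray
    convergence_rate: float
    n_scenes: int

    @property
    def median_error_mm(self) -> float:
        return float(np.median(self.per_joint_errors_mm))

    @property
    def mean_error_mm(self) -> float:
        return float(np.mean(self.per_joint_errors_mm))


def build_default_priors(skeleton: SkeletonDefinition, seed: int):
    """Fit the pose and shape priors on freshly generated synthetic data."""
    rng = np.random.default_rng(seed)
    poses = sample_pose_collection(skeleton, N_POSE_PRIOR_TRAINING,
                                   seed=int(rng.integers(2 ** 31)))
    pose_prior = fit_pose_prior(poses, seed=int(rng.integers(2 ** 31)),
                                joint_names=skeleton.joint_names)
    cohort = sample_cohort_bone_lengths(N_COHORT_SPECIMENS, N_COHORT_GROUPS,
                                        seed=int(rng.integers(2 ** 31)),
                                        skeleton=skeleton)
    shape_prior = fit_shape_prior(cohort, seed=int(rng.integers(2 ** 31)))
    return pose_prior, shape_prior, cohort


def _random_scene(skeleton, camera, rng, noise_sigma_px, occlusion_fraction):
    pose = sample_pose(skeleton, "gait", seed=int(rng.integers(2 ** 31)))
    ri = skeleton.root_index
    pose.angles[3 * ri + 2] = rng.uniform(-np.pi, np.pi)
    pose.root_translation = np.array(
        [rng.uniform(-20, 20), rng.uniform(-20, 20), 30.0])
    scene = render_scene(skeleton, pose, [camera], noise_sigma_px,
                         occlusion_fraction,
                         seed=int(rng.integers(2 ** 31)))
    distance = float(np.linalg.norm(pose.root_translation - camera.center))
    return scene, distance


def single_view_recovery(skeleton: SkeletonDefinition,
                         pose_prior, shape_prior,
                         n_scenes: int, seed: int,
                         noise_sigma_px: float = 0.0,
                         occlusion_fraction: float = 0.0,
                         camera: CameraModel | None = None) -> RecoveryResult:
    """Lift seeded synthetic scenes at the true fixed distance and measure
    per-joint 3D errors against the generating pose."""
    camera = camera or default_rig()[0]
    rng = np.random.default_rng(seed)
    errors, scene_medians = [], []
    n_converged = 0
    n = skeleton.n_joints
    for _ in range(n_scenes):
        scene, distance = _random_scene(skeleton, camera, rng,
                                        noise_sigma_px, occlusion_fraction)
        config = EnergyConfig(fixed_distance=distance)
        fit = optimize_pose(scene.observations[0], camera, skeleton,
                            pose_prior, shape_prior, config)
        n_converged += fit.converged
        kp = forward_kinematics(skeleton, fit.pose)
        err = np.linalg.norm(
            kp.positions[:n] - scene.true_keypoints.positions[:n], axis=1)
        errors.append(err)
        scene_medians.append(np.median(err))
    return RecoveryResult(
        per_joint_errors_mm=np.concatenate(errors),
        per_scene_median_mm=np.asarray(scene_medians),
        convergence_rate=n_converged / n_scenes,
        n_scenes=n_scenes)


def multiview_recovery(skeleton: SkeletonDefinition, n_scenes: int,
                       seed: int) -> dict:
    """Noiseless 3-camera triangulation of seeded scenes.

    Returns the worst keypoint error (mm) and the worst gap by which the
    refined reprojection RMSE could exceed the DLT initialization (a
    correct refinement never lets this go positive).
    """
    from .geometry import reconstruct_pose_multiview, triangulate
    rig = default_rig()
    rng = np.random.default_rng(seed)
    max_err = 0.0
    worst_refinement_gap = -np.inf
    for _ in range(n_scenes):
        scene, _ = _random_scene(skeleton, rig[0], rng, 0.0, 0.0)
        scene = render_scene(skeleton, scene.true_pose, rig, 0.0, 0.0,
                             seed=int(rng.integers(2 ** 31)))
        rec = reconstruct_pose_multiview(scene.observations, rig)
        err = np.linalg.norm(
            rec.positions - scene.true_keypoints.positions, axis=1)
        max_err = max(max_err, float(err.max()))
        # refinement property measured on noisy observations, where the
        # DLT initialization is genuinely suboptimal
        for i in range(0, len(rec.names), 7):
            obs = [o.uv[i] + rng.normal(0, 2.0, 2)
                   for o in scene.observations]
            result = triangulate(obs, rig)
            worst_refinement_gap = max(
                worst_refinement_gap, result.rmse_px - result.dlt_rmse_px)
    return {"max_error_mm": max_err,
            "worst_refinement_gap_px": float(worst_refinement_gap)}


def shape_prior_cluster_recovery(cohort, shape_prior, skeleton) -> float:
    """Fraction of specimens whose dominant mixture component lies nearest
    their own size-group mean."""
    bones = list(skeleton.bone_names)
    X = cohort[bones].to_numpy()
    groups = cohort["group"].to_numpy()
    group_means = np.stack([X[groups == g].mean(axis=0)
                            for g in np.unique(groups)])
    assigned = shape_prior.responsibilities(X).argmax(axis=1)
    hits = 0
    for i in range(len(X)):
        nearest = np.argmin(np.linalg.norm(
            group_means - shape_prior.means[assigned[i]], axis=1))
        hits += nearest == groups[i]
    return hits / len(X)


def pose_prior_ranking(skeleton, pose_prior, n_trials: int,
                       seed: int) -> float:
    """Fraction of trials where an in-distribution (gait) pose scores a
    lower prior NLL than a uniformly random pose."""
    rng = np.random.default_rng(seed)
    wins = 0
    for _ in range(n_trials):
        gait = sample_pose(skeleton, "gait", seed=int(rng.integers(2 ** 31)))
        rand = sample_pose(skeleton, "random",
                           seed=int(rng.integers(2 ** 31)))
        rand.bone_lengths = gait.bone_lengths.copy()
        nll_g = neg_log_likelihood(pose_prior, normalize_pose(
            forward_kinematics(skeleton, gait),
            skeleton.joint_names).flatten())
        nll_r = neg_log_likelihood(pose_prior, normalize_pose(
            forward_kinematics(skeleton, rand),
            skeleton.joint_names).flatten())
        wins += nll_g < nll_r
    return wins / n_trials
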