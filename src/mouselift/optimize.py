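"""Monocular 3D pose lifting by energy minimization.

Given one camera view's 2D keypoints, the optimizer updates the joint
angles ``a`` and bone lengths ``l`` of the kinematic chain to minimize

    E(a, l) = sum_i || proj(T(a, l))_i - k_i ||^2
              + lambda_p * p_p(a) + lambda_s * p_s(l)

where the sum runs over usable observed keypoints (pixel units) and the
pose/shape priors enter as Gaussian-mixture negative log-likelihoods.  A
single view cannot separate body size from distance, so the root joint is
constrained to a fixed, known distance from the camera centre and
parameterized by the two coordinates of its viewing ray; bone lengths are
optimized in log-space to stay positive.

The solver is trust-region-reflective least squares.  Inside it, each
mixture penalty is represented by the Mahalanobis whitened residual vector
of its currently dominant component (``sqrt(lambda/2) L_j^{-1}(x - mu_j)``
with ``j`` the highest-responsibility component): this equals the mixture
NLL up to a locally constant offset while exposing the penalty's full
curvature to the Gauss-Newton model, which a single scalar sqrt-NLL row
cannot.  Reported energies always use the exact mixture NLL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .geometry import (BehindCameraError, CameraModel, ObservedKeypoints2D,
                       _distort)
from .priors import GmmPrior, normalize_points
from .skeleton import PoseState, SkeletonDefinition, _global_transforms

__all__ = [
    "EnergyConfig",
    "EnergyBreakdown",
    "PoseFit",
    "energy",
    "initialize_pose",
    "optimize_pose",
    "lift_sequence",
    "TooFewKeypointsError",
]


class TooFewKeypointsError(ValueError):
    """Fewer usable 2D keypoints than the optimizer needs."""


@dataclass
class EnergyConfig:
    """Weights, constraint and stopping rules for the lifting energy.

    ``fixed_distance`` is the required root-to-camera-centre distance in mm
    (rig-specific; it resolves the monocular scale/depth ambiguity).
    ``lambda_pose`` is deliberately small: the pose prior should gently keep
    the solution plausible without pinning it to the mixture modes, while
    ``lambda_shape`` is larger because bone lengths are only weakly
    constrained by a single view.  Keypoints with confidence below
    ``confidence_floor`` are excluded from the residual.
    """

    fixed_distance: float
    lambda_pose: float = 1e-2
    lambda_shape: float = 1e-1
    max_iterations: int = 300
    step_tolerance: float = 1e-10
    residual_tolerance: float = 1e-12
    confidence_floor: float = 0.05
    min_keypoints: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fixed_distance <= 0:
            raise ValueError("fixed_distance must be positive")
        if self.lambda_pose < 0 or self.lambda_shape < 0:
            raise ValueError("penalty weights must be nonnegative")
        if self.step_tolerance <= 0 or self.residual_tolerance <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class EnergyBreakdown:
    reprojection: float
    pose_nll: float
    shape_nll: float
    lambda_pose: float
    lambda_shape: float
    n_keypoints_used: int
    excluded_keypoints: tuple[str, ...]

    @property
    def total(self) -> float:
        return (self.reprojection + self.lambda_pose * self.pose_nll
                + self.lambda_shape * self.shape_nll)


@dataclass
class PoseFit:
    """Result of one frame's lift."""

    pose: PoseState | None
    energy_trace: np.ndarray
    final_energy: float
    final_reprojection_rmse: float
    breakdown: EnergyBreakdown | None
    converged: bool
    excluded_keypoints: tuple[str, ...]
    message: str = ""
    error: str | None = None
    used_fallback_init: bool = False


class _Problem:
    """Precomputed residual context for one frame."""

    def __init__(self, observations: ObservedKeypoints2D,
                 camera: CameraModel, skeleton: SkeletonDefinition,
                 pose_prior: GmmPrior | None, shape_prior: GmmPrior | None,
                 config: EnergyConfig):
        self.camera = camera
        self.skeleton = skeleton
        self.config = config
        self.pose_prior = pose_prior if config.lambda_pose > 0 else None
        self.shape_prior = shape_prior if config.lambda_shape > 0 else None
        names = skeleton.joint_names
        self.include: list[int] = []   # joint indices with usable obs
        obs_uv: list[np.ndarray] = []
        excluded = []
        for i, name in enumerate(observations.names):
            if name not in names:
                continue  # derived markers (ears) never enter the residual
            if observations.confidence[i] >= config.confidence_floor:
                self.include.append(names.index(name))
                obs_uv.append(observations.uv[i])
            else:
                excluded.append(name)
        self.excluded = tuple(excluded)
        self.obs = np.asarray(obs_uv, dtype=float).reshape(-1, 2)
        self.norm_idx = (names.index("upper_spine"),
                         names.index("middle_spine"),
                         (names.index("left_hip"), names.index("right_hip")))
        self.energy_log: list[float] = []
        n = skeleton.n_joints
        # explicit parameter scaling: radians, log-lengths, ray coordinates
        self.x_scale = np.concatenate(
            [np.full(3 * n, 1.0), np.full(n - 1, 0.2), [0.05, 0.05]])

    # -- parameter vector <-> pose -------------------------------------
    def root_from_ray(self, rx: float, ry: float) -> np.ndarray:
        d = np.array([rx, ry, 1.0])
        d /= np.linalg.norm(d)
        root_cam = self.config.fixed_distance * d
        return self.camera.rotation.T @ (root_cam - self.camera.translation)

    def ray_from_root(self, root_world: np.ndarray) -> tuple[float, float]:
        rc = self.camera.world_to_camera(root_world[None])[0]
        if rc[2] <= 0:
            raise BehindCameraError("initial root behind the camera")
        return rc[0] / rc[2], rc[1] / rc[2]

    def pack(self, pose: PoseState) -> np.ndarray:
        rx, ry = self.ray_from_root(pose.root_translation)
        return np.concatenate(
            [pose.angles, np.log(pose.bone_lengths), [rx, ry]])

    def unpack(self, x: np.ndarray) -> PoseState:
        n = self.skeleton.n_joints
        return PoseState(angles=x[:3 * n],
                         bone_lengths=np.exp(x[3 * n:3 * n + n - 1]),
                         root_translation=self.root_from_ray(x[-2], x[-1]))

    # -- residuals ------------------------------------------------------
    def terms(self, pose: PoseState, clamp: bool = True):
        """(pixel residuals, pose features or None, pose NLL, shape NLL)."""
        _, P = _global_transforms(self.skeleton, pose)
        cam = self.camera
        pc = P[self.include] @ cam.rotation.T + cam.translation
        z = pc[:, 2]
        if np.any(z <= 1e-6):
            if not clamp:
                raise BehindCameraError("joint at or behind the camera")
            z = np.maximum(z, 1e-6)
        xn = pc[:, :2] / z[:, None]
        xn = _distort(xn, cam.distortion)
        uv = np.empty_like(xn)
        uv[:, 0] = cam.fx * xn[:, 0] + cam.cx
        uv[:, 1] = cam.fy * xn[:, 1] + cam.cy
        pix = (uv - self.obs).ravel()
        feats = None
        p_nll = s_nll = 0.0
        if self.pose_prior is not None:
            feats = normalize_points(P, *self.norm_idx).ravel()
            p_nll = -float(self.pose_prior.log_density(feats[None])[0])
        if self.shape_prior is not None:
            s_nll = -float(self.shape_prior.log_density(
                pose.bone_lengths[None])[0])
        return pix, feats, p_nll, s_nll

    def residuals(self, x: np.ndarray) -> np.ndarray:
        pose = self.unpack(x)
        pix, feats, p_nll, s_nll = self.terms(pose, clamp=True)
        cfg = self.config
        self.energy_log.append(
            float(pix @ pix) + cfg.lambda_pose * p_nll
            + cfg.lambda_shape * s_nll)
        rows = [pix]
        if self.pose_prior is not None:
            pp = self.pose_prior
            j = int(np.argmax(pp._component_logpdf(feats[None])[0]))
            rows.append(np.sqrt(cfg.lambda_pose / 2.0)
                        * (pp._chol_inv[j] @ (feats - pp.means[j])))
        if self.shape_prior is not None:
            sp = self.shape_prior
            l = pose.bone_lengths
            j = int(np.argmax(sp._component_logpdf(l[None])[0]))
            rows.append(np.sqrt(cfg.lambda_shape / 2.0)
                        * (sp._chol_inv[j] @ (l - sp.means[j])))
        return np.concatenate(rows)


def energy(pose: PoseState, observations: ObservedKeypoints2D,
           camera: CameraModel, skeleton: SkeletonDefinition,
           pose_prior: GmmPrior | None, shape_prior: GmmPrior | None,
           config: EnergyConfig) -> tuple[float, EnergyBreakdown]:
    """Evaluate the lifting energy and its term-wise breakdown.

    The total is exactly ``reprojection + lambda_p * pose_nll +
    lambda_s * shape_nll``.  Raises if no keypoint clears the confidence
    floor or if a chain joint lies behind the camera.
    """
    prob = _Problem(observations, camera, skeleton, pose_prior, shape_prior,
                    config)
    if len(prob.include) == 0:
        raise TooFewKeypointsError("no keypoints above the confidence floor")
    pix, _, p_nll, s_nll = prob.terms(pose, clamp=False)
    breakdown = EnergyBreakdown(
        reprojection=float(pix @ pix), pose_nll=p_nll, shape_nll=s_nll,
        lambda_pose=config.lambda_pose, lambda_shape=config.lambda_shape,
        n_keypoints_used=len(prob.include),
        excluded_keypoints=prob.excluded)
    return breakdown.total, breakdown


def initialize_pose(observations: ObservedKeypoints2D, camera: CameraModel,
                    skeleton: SkeletonDefinition, config: EnergyConfig,
                    shape_prior: GmmPrior | None = None,
                    with_info: bool = False):
    """Deterministic starting pose for the optimizer.

    Rest-pose angles; the root is placed on the back-projected viewing ray
    of the lower-spine observation at the configured fixed distance, with
    the body yaw (rotation about the world vertical) set from the observed
    2D lower-to-upper-spine direction.  Bone lengths start at the shape
    prior's mixture mean when a prior is supplied, else at the skeleton
    defaults.  If the spine points are unusable the root falls back to the
    centroid ray of whatever points are available (flagged in the info
    dict when ``with_info``).
    """
    names = observations.names
    conf = observations.confidence

    def usable(name: str) -> bool:
        return (name in names
                and conf[names.index(name)] >= config.confidence_floor)

    fallback = False
    if usable("lower_spine"):
        anchor_uv = observations.get("lower_spine")
    else:
        fallback = True
        finite = np.isfinite(observations.uv).all(axis=1)
        anchor_uv = (observations.uv[finite].mean(axis=0) if finite.any()
                     else np.array([camera.cx, camera.cy]))

    xn = np.array([(anchor_uv[0] - camera.cx) / camera.fx,
                   (anchor_uv[1] - camera.cy) / camera.fy, 1.0])
    d_cam = xn / np.linalg.norm(xn)
    root_world = camera.rotation.T @ (
        config.fixed_distance * d_cam - camera.translation)

    yaw = 0.0
    if usable("lower_spine") and usable("upper_spine"):
        duv = observations.get("upper_spine") - observations.get("lower_spine")
        s_cam = np.array([duv[0] / camera.fx, duv[1] / camera.fy, 0.0])
        s_world = camera.rotation.T @ s_cam
        s_h = s_world - s_world[2] * np.array([0.0, 0.0, 1.0])
        if np.linalg.norm(s_h) > 1e-12:
            # rest pose points the root->upper_spine axis along -x
            yaw = np.arctan2(s_h[1], s_h[0]) + np.pi
    else:
        fallback = True

    lengths = (shape_prior.mean() if shape_prior is not None
               else skeleton.default_bone_lengths)
    angles = np.zeros(3 * skeleton.n_joints)
    angles[3 * skeleton.root_index + 2] = yaw  # rotation about world z
    pose = PoseState(angles=angles, bone_lengths=np.asarray(lengths),
                     root_translation=root_world)
    if with_info:
        return pose, {"used_fallback": fallback, "yaw": yaw}
    return pose


def optimize_pose(observations: ObservedKeypoints2D, camera: CameraModel,
                  skeleton: SkeletonDefinition,
                  pose_prior: GmmPrior | None, shape_prior: GmmPrior | None,
                  config: EnergyConfig,
                  initial: PoseState | None = None) -> PoseFit:
    """Fit one frame: trust-region least squares on the lifting energy.

    The root stays on the sphere of radius ``config.fixed_distance`` about
    the camera centre throughout (it is parameterized by its viewing ray).
    Non-convergence is reported via ``converged=False``, not an exception;
    fewer than ``config.min_keypoints`` usable keypoints is an error.
    """
    prob = _Problem(observations, camera, skeleton, pose_prior, shape_prior,
                    config)
    if len(prob.include) < config.min_keypoints:
        raise TooFewKeypointsError(
            f"need at least {config.min_keypoints} usable keypoints, "
            f"got {len(prob.include)}")
    used_fallback = False
    if initial is None:
        initial, info = initialize_pose(observations, camera, skeleton,
                                        config, shape_prior, with_info=True)
        used_fallback = info["used_fallback"]
    x0 = prob.pack(initial)
    res = least_squares(
        prob.residuals, x0, method="trf", jac="2-point",
        xtol=config.step_tolerance, ftol=config.residual_tolerance,
        max_nfev=config.max_iterations, x_scale=prob.x_scale)
    pose = prob.unpack(res.x)
    pix, _, p_nll, s_nll = prob.terms(pose, clamp=True)
    breakdown = EnergyBreakdown(
        reprojection=float(pix @ pix), pose_nll=p_nll, shape_nll=s_nll,
        lambda_pose=config.lambda_pose, lambda_shape=config.lambda_shape,
        n_keypoints_used=len(prob.include),
        excluded_keypoints=prob.excluded)
    rmse = float(np.sqrt(breakdown.reprojection / (2 * len(prob.include))))
    # best-energy-so-far trace over solver evaluations: monotone record of
    # accepted progress (trial evaluations that increased E are not steps)
    trace = np.minimum.accumulate(np.asarray(prob.energy_log))
    return PoseFit(pose=pose, energy_trace=trace,
                   final_energy=breakdown.total,
                   final_reprojection_rmse=rmse,
                   breakdown=breakdown,
                   converged=bool(res.status > 0),
                   excluded_keypoints=prob.excluded,
                   message=res.message,
                   used_fallback_init=used_fallback)


def lift_sequence(observation_seq: Sequence[ObservedKeypoints2D],
                  camera: CameraModel, skeleton: SkeletonDefinition,
                  pose_prior: GmmPrior | None, shape_prior: GmmPrior | None,
                  config: EnergyConfig) -> list[PoseFit]:
    """Lift a sequence of frames, warm-starting each from the previous fit.

    Frames that fail (e.g. every keypoint occluded) yield a ``PoseFit``
    with ``error`` set and ``pose=None``; subsequent frames fall back to the
    last successful solution, or to a cold start if there is none.
    """
    if len(observation_seq) == 0:
        raise ValueError("need at least one frame")
    fits: list[PoseFit] = []
    warm: PoseState | None = None
    for obs in observation_seq:
        try:
            fit = optimize_pose(obs, camera, skeleton, pose_prior,
                                shape_prior, config, initial=warm)
        except (TooFewKeypointsError, BehindCameraError) as exc:
            fit = PoseFit(pose=None, energy_trace=np.empty(0),
                          final_energy=np.nan,
                          final_reprojection_rmse=np.nan, breakdown=None,
                          converged=False, excluded_keypoints=(),
                          error=str(exc))
        fits.append(fit)
        if fit.pose is not None:
            warm = fit.pose
    return fits
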