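"""Synthetic ground truth: skeleton poses, camera rigs, and gait traces.

Every reconstruction stage in this package is exercised against data whose
true parameters are known.  This module generates them: articulated poses
via forward kinematics, a three-camera capture rig (one top-down camera
over the cage plus two side cameras, mirroring a typical multiview rig),
projected 2D observations with Gaussian pixel noise and zero-confidence
occlusions, per-specimen bone-length cohorts grouped by body size, and
periodic foot traces of known frequency for the gait estimators.  All
generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait import FootTrace
from .geometry import CameraModel, ObservedKeypoints2D, look_at, project
from .skeleton import (Keypoints3D, PoseState, SkeletonDefinition,
                       forward_kinematics)

__all__ = [
    "SyntheticScene",
    "default_rig",
    "sample_cohort_bone_lengths",
    "sample_pose",
    "sample_pose_collection",
    "render_scene",
    "make_gait_trace",
]

GAIT_AMPLITUDE_RAD = np.deg2rad(30.0)
RANDOM_ANGLE_RANGE_RAD = np.deg2rad(45.0)
COHORT_CV = 0.03  # within-group coefficient of variation of bone lengths

_LIMB_ROOTS = {"left_shoulder": 0, "right_shoulder": np.pi,
               "left_hip": np.pi, "right_hip": 0}
_LIMB_MIDS = {"left_elbow": 0, "right_elbow": np.pi,
              "left_knee": np.pi, "right_knee": 0}


@dataclass
class SyntheticScene:
    """A posed skeleton observed by a calibrated rig, with ground truth."""

    skeleton: SkeletonDefinition
    true_pose: PoseState
    true_keypoints: Keypoints3D
    cameras: list[CameraModel]
    observations: list[ObservedKeypoints2D]
    noise_sigma_px: float
    occluded_names: tuple[str, ...]
    seed: int


def default_rig(center=(0.0, 0.0, 30.0), top_height: float = 400.0,
                side_distance: float = 450.0, side_height: float = 80.0,
                fx: float = 800.0, image_size=(640, 480)) -> list[CameraModel]:
    """Three-camera rig: one top-down view plus two side views 90 deg apart.

    ``center`` is the nominal animal position (mm, world frame with z up
    from the cage floor); cameras are aimed at it.
    """
    center = np.asarray(center, dtype=float)
    w, h = image_size
    placements = [
        center + [0.0, 0.0, top_height],
        center + [side_distance, 0.0, side_height - center[2]],
        center + [0.0, side_distance, side_height - center[2]],
    ]
    cameras = []
    for pos in placements:
        R, t = look_at(pos, center)
        cameras.append(CameraModel(fx=fx, fy=fx, cx=w / 2.0, cy=h / 2.0,
                                   rotation=R, translation=t,
                                   image_size=(w, h)))
    return cameras


def sample_cohort_bone_lengths(n_specimens: int, n_groups: int,
                               seed: int,
                               skeleton: SkeletonDefinition | None = None
                               ) -> pd.DataFrame:
    """Bone-length table for a synthetic cohort grouped by body size.

    Groups emulate weight/sex strata: each group scales the canonical adult
    lengths by a factor spread over 0.85-1.15, with 3% within-group
    coefficient of variation per bone.  Returns one row per specimen with
    the 17 bone columns plus a ``group`` column.
    """
    if n_specimens < n_groups:
        raise ValueError("need at least one specimen per group")
    from .skeleton import build_default_mouse_skeleton
    skeleton = skeleton or build_default_mouse_skeleton()
    rng = np.random.default_rng(seed)
    base = skeleton.default_bone_lengths
    scales = np.linspace(0.85, 1.15, n_groups)
    groups = np.array([(i * n_groups) // n_specimens
                       for i in range(n_specimens)])
    rows = base[None, :] * scales[groups][:, None] * (
        1.0 + COHORT_CV * rng.standard_normal((n_specimens, base.size)))
    rows = np.maximum(rows, 0.1)
    table = pd.DataFrame(rows, columns=list(skeleton.bone_names))
    table["group"] = groups
    return table


def sample_pose(skeleton: SkeletonDefinition, mode: str = "gait",
                phase: float | None = None, seed: int = 0,
                bone_lengths: np.ndarray | None = None) -> PoseState:
    """Draw a pose: ``rest`` (zero angles), ``gait`` or ``random``.

    Gait poses swing each limb sinusoidally with +-30 deg amplitude about
    the left-right axis, left and right limbs in antiphase; the stride
    phase is ``phase`` (drawn uniformly when omitted).  Random poses draw
    every angle component uniformly in +-45 deg.  Bone lengths default to
    a seeded row of the synthetic cohort, so sampled animals carry
    realistic size and shape variation.
    """
    rng = np.random.default_rng(seed)
    n = skeleton.n_joints
    angles = np.zeros(3 * n)
    if bone_lengths is not None:
        lengths = np.asarray(bone_lengths, dtype=float)
    elif mode == "rest":
        lengths = skeleton.default_bone_lengths.copy()
    else:
        cohort = sample_cohort_bone_lengths(
            8, 4, seed=int(rng.integers(2 ** 31)), skeleton=skeleton)
        row = int(rng.integers(len(cohort)))
        lengths = cohort.iloc[row][list(skeleton.bone_names)].to_numpy(
            dtype=float)
    if mode == "rest":
        pass
    elif mode == "gait":
        if phase is None:
            phase = float(rng.uniform(0.0, 2 * np.pi))
        for name, offset in _LIMB_ROOTS.items():
            j = skeleton.joint_index(name)
            angles[3 * j + 1] = GAIT_AMPLITUDE_RAD * np.cos(phase + offset)
        for name, offset in _LIMB_MIDS.items():
            j = skeleton.joint_index(name)
            angles[3 * j + 1] = 0.6 * GAIT_AMPLITUDE_RAD * np.cos(
                phase + offset + np.pi / 2)
    elif mode == "random":
        angles = rng.uniform(-RANDOM_ANGLE_RANGE_RAD, RANDOM_ANGLE_RANGE_RAD,
                             size=3 * n)
    else:
        raise ValueError(f"unknown pose mode {mode!r}")
    return PoseState(angles=angles, bone_lengths=lengths,
                     root_translation=np.zeros(3))


def sample_pose_collection(skeleton: SkeletonDefinition, n: int, seed: int,
                           mode: str = "gait") -> list[Keypoints3D]:
    """FK keypoint sets for ``n`` seeded poses (for pose-prior fitting)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        pose = sample_pose(skeleton, mode=mode,
                           seed=int(rng.integers(2 ** 31)))
        out.append(forward_kinematics(skeleton, pose))
    return out


def render_scene(skeleton: SkeletonDefinition, pose: PoseState,
                 cameras: list[CameraModel], noise_sigma_px: float = 0.0,
                 occlusion_fraction: float = 0.0,
                 seed: int = 0) -> SyntheticScene:
    """Project a posed skeleton into every camera of a rig.

    Adds i.i.d. Gaussian pixel noise and marks ``floor(fraction * n)``
    randomly chosen keypoints occluded (confidence 0) — the same names in
    every view, as when a body part is hidden under the animal.
    """
    rng = np.random.default_rng(seed)
    kp3d = forward_kinematics(skeleton, pose)
    names = kp3d.names
    n_occ = int(np.floor(occlusion_fraction * len(names)))
    occluded = tuple(sorted(
        rng.choice(names, size=n_occ, replace=False))) if n_occ else ()
    conf = np.array([0.0 if name in occluded else 1.0 for name in names])
    observations = []
    for cam in cameras:
        uv = project(cam, kp3d.positions)
        if noise_sigma_px > 0:
            uv = uv + rng.normal(0.0, noise_sigma_px, size=uv.shape)
        observations.append(
            ObservedKeypoints2D(names=names, uv=uv, confidence=conf.copy()))
    return SyntheticScene(skeleton=skeleton, true_pose=pose,
                          true_keypoints=kp3d, cameras=cameras,
                          observations=observations,
                          noise_sigma_px=noise_sigma_px,
                          occluded_names=occluded, seed=seed)


def make_gait_trace(frequency_hz: float, fps: float, duration_s: float,
                    amplitude: float = 1.0, noise_sigma: float = 0.0,
                    drift_per_s: float = 0.0, seed: int = 0,
                    joint_name: str = "left_ankle") -> FootTrace:
    """Sinusoidal foot trace with optional linear drift and Gaussian noise.

    The frequency must respect Nyquist (< fps/2); violating it would alias
    the stride peak.
    """
    if frequency_hz >= fps / 2.0:
        raise ValueError("frequency must be below the Nyquist rate fps/2")
    rng = np.random.default_rng(seed)
    t = np.arange(int(round(duration_s * fps))) / fps
    samples = (amplitude * np.sin(2 * np.pi * frequency_hz * t)
               + drift_per_s * t)
    if noise_sigma > 0:
        samples = samples + rng.normal(0.0, noise_sigma, size=t.size)
    return FootTrace(samples=samples, fps=fps, joint_name=joint_name)
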