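"""Mouse kinematic chain: skeleton definition and forward kinematics.

The animal is modelled as a tree of 18 spherical joints (3 rotational
degrees of freedom each, 54 in total) connected by rigid bones.  Joint
angles ``a`` (axis-angle rotation vectors, composed down the chain) and
bone lengths ``l`` (millimetres) determine all 3D joint positions through
forward kinematics ``T(a, l)``.  The two ear keypoints are derived markers
rigidly attached to the head segment; they complete the 20-keypoint set
used for 2D annotation but are not chain joints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

__all__ = [
    "SkeletonDefinition",
    "PoseState",
    "Keypoints3D",
    "build_default_mouse_skeleton",
    "load_skeleton",
    "save_skeleton",
    "forward_kinematics",
    "fk_jacobian",
    "count_dof",
    "bone_lengths_from_keypoints",
]

class SkeletonError(ValueError):
    """Raised for structurally invalid skeletons or mismatched poses."""


@dataclass(frozen=True)
class SkeletonDefinition:
    """An articulated kinematic tree plus its keypoint naming map.

    Parameters
    ----------
    joint_names:
        Ordered joint identifiers; parents must precede children.
    parent_index:
        Per-joint index of the parent joint; ``-1`` marks the single root.
    rest_directions:
        ``(n_joints, 3)`` unit vectors from parent to joint in the parent's
        frame at rest.  The root row is ignored (stored as zeros).
    keypoint_names:
        The full marker set: every joint name plus derived markers (ears).
    marker_offsets:
        Derived (non-joint) keypoints: ``name -> (anchor_joint, offset)``
        where ``offset`` is expressed in the anchor joint's frame as a
        fraction of the anchor's bone length.
    default_bone_lengths:
        Per non-root joint (in joint order), rest bone length in mm.
    """

    joint_names: tuple[str, ...]
    parent_index: np.ndarray
    rest_directions: np.ndarray
    keypoint_names: tuple[str, ...]
    marker_offsets: Mapping[str, tuple[str, np.ndarray]]
    default_bone_lengths: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.joint_names)
        parents = np.asarray(self.parent_index, dtype=int)
        dirs = np.asarray(self.rest_directions, dtype=float)
        object.__setattr__(self, "parent_index", parents)
        object.__setattr__(self, "rest_directions", dirs)
        object.__setattr__(
            self, "default_bone_lengths",
            np.asarray(self.default_bone_lengths, dtype=float))
        if n == 0:
            raise SkeletonError("skeleton must contain at least one joint")
        if len(set(self.joint_names)) != n:
            raise SkeletonError("duplicate joint names")
        if parents.shape != (n,) or dirs.shape != (n, 3):
            raise SkeletonError("parent_index/rest_directions shape mismatch")
        roots = np.flatnonzero(parents < 0)
        if roots.size != 1:
            raise SkeletonError(f"expected exactly one root, found {roots.size}")
        # parents must precede children => acyclic and topologically ordered
        for i, p in enumerate(parents):
            if p >= i:
                raise SkeletonError(
                    "joints must be listed parent-first (acyclic tree)")
        nonroot = parents >= 0
        norms = np.linalg.norm(dirs[nonroot], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise SkeletonError("rest directions must be unit vectors")
        dirs[nonroot] /= norms[:, None]  # tighten to 1e-16
        if self.default_bone_lengths.shape != (n - 1,):
            raise SkeletonError("need one default length per non-root joint")
        if np.any(self.default_bone_lengths <= 0):
            raise SkeletonError("default bone lengths must be positive")
        missing = set(self.joint_names) - set(self.keypoint_names)
        if missing:
            raise SkeletonError(f"keypoint_names must cover all joints: {missing}")
        for name, (anchor, _) in self.marker_offsets.items():
            if name in self.joint_names or anchor not in self.joint_names:
                raise SkeletonError(f"bad derived marker {name!r}")

    @property
    def n_joints(self) -> int:
        return len(self.joint_names)

    @property
    def root_index(self) -> int:
        return int(np.flatnonzero(self.parent_index < 0)[0])

    @property
    def bone_joint_indices(self) -> np.ndarray:
        """Joint index of each bone's distal end, in bone order."""
        return np.flatnonzero(self.parent_index >= 0)

    @property
    def bone_names(self) -> tuple[str, ...]:
        return tuple(self.joint_names[j] for j in self.bone_joint_indices)

    def joint_index(self, name: str) -> int:
        return self.joint_names.index(name)

    def rest_pose(self, bone_lengths: np.ndarray | None = None,
                  root_translation: Sequence[float] = (0.0, 0.0, 0.0)) -> "PoseState":
        """All joint angles zero; default bone lengths unless given."""
        lengths = (self.default_bone_lengths if bone_lengths is None
                   else np.asarray(bone_lengths, dtype=float))
        return PoseState(
            angles=np.zeros(3 * self.n_joints),
            bone_lengths=lengths,
            root_translation=np.asarray(root_translation, dtype=float),
        )


@dataclass
class PoseState:
    """Pose parameters: 54 joint angles, 17 bone lengths, root placement.

    ``angles`` holds one axis-angle rotation vector (radians) per joint in
    skeleton joint order; the root joint's three angles are the global body
    orientation.  ``root_translation`` is the root joint position in the
    world frame, millimetres.
    """

    angles: np.ndarray
    bone_lengths: np.ndarray
    root_translation: np.ndarray = field(
        default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float).ravel()
        self.bone_lengths = np.asarray(self.bone_lengths, dtype=float).ravel()
        self.root_translation = np.asarray(
            self.root_translation, dtype=float).ravel()
        if self.angles.size % 3 != 0:
            raise SkeletonError("angles must hold 3 values per joint")
        if np.any(self.bone_lengths <= 0):
            raise SkeletonError("bone lengths must be strictly positive")
        if self.root_translation.shape != (3,):
            raise SkeletonError("root_translation must be a 3-vector")

    @property
    def n_joints(self) -> int:
        return self.angles.size // 3

    def copy(self) -> "PoseState":
        return PoseState(self.angles.copy(), self.bone_lengths.copy(),
                         self.root_translation.copy())

    def check_matches(self, skeleton: SkeletonDefinition) -> None:
        if self.n_joints != skeleton.n_joints:
            raise SkeletonError(
                f"pose has {self.n_joints} joints, skeleton has "
                f"{skeleton.n_joints}")
        if self.bone_lengths.size != skeleton.n_joints - 1:
            raise SkeletonError("bone_lengths size mismatch")


@dataclass
class Keypoints3D:
    """Named 3D points (mm) with per-point validity flags."""

    names: tuple[str, ...]
    positions: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.names), 3):
            raise ValueError("positions must be (n_names, 3)")
        if self.valid is None:
            self.valid = np.ones(len(self.names), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool).ravel()
        if not np.all(np.isfinite(self.positions[self.valid])):
            raise ValueError("valid keypoint positions must be finite")

    def get(self, name: str) -> np.ndarray:
        return self.positions[self.names.index(name)]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {n: self.positions[i] for i, n in enumerate(self.names)
                if self.valid[i]}

    def subset(self, names: Sequence[str]) -> "Keypoints3D":
        idx = [self.names.index(n) for n in names]
        return Keypoints3D(tuple(names), self.positions[idx], self.valid[idx])


def load_skeleton(source) -> SkeletonDefinition:
    """Load a skeleton from a YAML path, file object, or parsed mapping."""
    if isinstance(source, Mapping):
        spec = source
    elif hasattr(source, "read"):
        spec = yaml.safe_load(source.read())
    else:
        with open(source) as fh:
            spec = yaml.safe_load(fh)
    joints = spec["joints"]
    names = [j["name"] for j in joints]
    index = {n: i for i, n in enumerate(names)}
    parents = np.array(
        [-1 if j["parent"] is None else index[j["parent"]] for j in joints])
    dirs = np.zeros((len(joints), 3))
    lengths = []
    for i, j in enumerate(joints):
        if parents[i] >= 0:
            d = np.asarray(j["rest_direction"], dtype=float)
            dirs[i] = d / np.linalg.norm(d)
            lengths.append(float(j["default_length"]))
    markers = {
        name: (m["anchor"], np.asarray(m["offset"], dtype=float))
        for name, m in spec.get("ear_markers", {}).items()
    }
    return SkeletonDefinition(
        joint_names=tuple(names),
        parent_index=parents,
        rest_directions=dirs,
        keypoint_names=tuple(names) + tuple(markers),
        marker_offsets=markers,
        default_bone_lengths=np.array(lengths),
    )


def save_skeleton(skeleton: SkeletonDefinition, path) -> None:
    joints = []
    bone_idx = {int(j): b for b, j in enumerate(skeleton.bone_joint_indices)}
    for i, name in enumerate(skeleton.joint_names):
        p = int(skeleton.parent_index[i])
        entry: dict = {"name": name,
                       "parent": None if p < 0 else skeleton.joint_names[p]}
        if p >= 0:
            entry["rest_direction"] = [float(v) for v in
                                       skeleton.rest_directions[i]]
            entry["default_length"] = float(
                skeleton.default_bone_lengths[bone_idx[i]])
        joints.append(entry)
    markers = {name: {"anchor": anchor, "offset": [float(v) for v in off]}
               for name, (anchor, off) in skeleton.marker_offsets.items()}
    with open(path, "w") as fh:
        yaml.safe_dump({"joints": joints, "ear_markers": markers}, fh,
                       sort_keys=False)


def build_default_mouse_skeleton() -> SkeletonDefinition:
    """The canonical 18-joint mouse chain with 20 named keypoints.

    Spine chain (nose, upper/middle/lower spine, tail base and tip) plus
    four three-segment limbs; rooted at the pelvis (lower spine, the
    midpoint between the hips).  Ears are derived head markers.
    """
    ref = resources.files("mouselift.data") / "mouse_skeleton.yaml"
    with ref.open() as fh:
        return load_skeleton(fh)


def _global_transforms(skeleton: SkeletonDefinition, pose: PoseState):
    """Cumulative rotations and joint positions down the chain."""
    n = skeleton.n_joints
    local = Rotation.from_rotvec(pose.angles.reshape(n, 3)).as_matrix()
    bone_of = np.full(n, -1)
    bone_of[skeleton.bone_joint_indices] = np.arange(n - 1)
    G = np.empty((n, 3, 3))
    P = np.empty((n, 3))
    for i in range(n):
        p = skeleton.parent_index[i]
        if p < 0:
            G[i] = local[i]
            P[i] = pose.root_translation
        else:
            G[i] = G[p] @ local[i]
            P[i] = P[p] + G[i] @ (skeleton.rest_directions[i]
                                  * pose.bone_lengths[bone_of[i]])
    return G, P


def forward_kinematics(skeleton: SkeletonDefinition,
                       pose: PoseState) -> Keypoints3D:
    """Map pose parameters to 3D keypoint positions, ``T(a, l)``.

    Each non-root joint sits at its parent's position plus the chain-
    composed rotation applied to its rest direction scaled by its bone
    length.  Derived markers (ears) are placed rigidly in their anchor
    joint's frame.  Returns all ``skeleton.keypoint_names``.
    """
    pose.check_matches(skeleton)
    G, P = _global_transforms(skeleton, pose)
    positions = {skeleton.joint_names[i]: P[i] for i in range(skeleton.n_joints)}
    bone_of = {int(j): b for b, j in enumerate(skeleton.bone_joint_indices)}
    for name, (anchor, offset) in skeleton.marker_offsets.items():
        a = skeleton.joint_index(anchor)
        scale = pose.bone_lengths[bone_of[a]] if a in bone_of else 1.0
        positions[name] = P[a] + G[a] @ (offset * scale)
    pts = np.stack([positions[n] for n in skeleton.keypoint_names])
    return Keypoints3D(skeleton.keypoint_names, pts)


def count_dof(skeleton: SkeletonDefinition) -> int:
    """Total rotational degrees of freedom: 3 per spherical joint."""
    return 3 * skeleton.n_joints


def bone_lengths_from_keypoints(skeleton: SkeletonDefinition,
                                points: Keypoints3D) -> np.ndarray:
    """Per-bone parent-to-child Euclidean distances (mm), in bone order.

    This is how a bone-length table is read off a set of 3D joint
    positions, e.g. landmarks placed on a CT scan or a multiview
    reconstruction.
    """
    pos = {}
    for name in skeleton.joint_names:
        if name not in points.names or not points.valid[points.names.index(name)]:
            raise SkeletonError(f"missing joint position: {name}")
        pos[name] = points.get(name)
    lengths = np.empty(skeleton.n_joints - 1)
    for b, j in enumerate(skeleton.bone_joint_indices):
        child = skeleton.joint_names[j]
        parent = skeleton.joint_names[skeleton.parent_index[j]]
        lengths[b] = np.linalg.norm(pos[child] - pos[parent])
    return lengths


def _right_jacobian_so3(r: np.ndarray) -> np.ndarray:
    """Right Jacobian of SO(3): exp(r + d) ~= exp(r) exp(J_r(r) d)."""
    theta = np.linalg.norm(r)
    K = np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0]])
    if theta < 1e-8:
        return np.eye(3) - 0.5 * K + K @ K / 6.0
    t2, t3 = theta * theta, theta ** 3
    return (np.eye(3) - (1 - np.cos(theta)) / t2 * K
            + (theta - np.sin(theta)) / t3 * (K @ K))


def fk_jacobian(skeleton: SkeletonDefinition, pose: PoseState):
    """Analytic Jacobian of joint positions w.r.t. pose parameters.

    Returns ``(J_angles, J_lengths, J_trans)`` with shapes
    ``(n_joints, 3, 3*n_joints)``, ``(n_joints, 3, n_joints-1)`` and
    ``(n_joints, 3, 3)``.  Rotating joint ``j``'s axis-angle vector moves
    every joint in its subtree about the joint's centre of rotation (the
    parent position; the root translation for the root), with the local
    perturbation mapped through the SO(3) right Jacobian.
    """
    pose.check_matches(skeleton)
    n = skeleton.n_joints
    G, P = _global_transforms(skeleton, pose)
    angles = pose.angles.reshape(n, 3)
    # subtree membership: desc[j, k] True if k is in subtree rooted at j
    desc = np.eye(n, dtype=bool)
    for k in range(n):
        p = skeleton.parent_index[k]
        if p >= 0:
            desc[:, k] |= desc[:, p]
    bone_of = np.full(n, -1)
    bone_of[skeleton.bone_joint_indices] = np.arange(n - 1)
    J_a = np.zeros((n, 3, 3 * n))
    J_l = np.zeros((n, 3, n - 1))
    J_t = np.tile(np.eye(3), (n, 1, 1))
    for j in range(n):
        p = skeleton.parent_index[j]
        centre = P[p] if p >= 0 else pose.root_translation
        A = (G[p] if p >= 0 else np.eye(3)) @ Rotation.from_rotvec(
            angles[j]).as_matrix() @ _right_jacobian_so3(angles[j])
        for k in range(n):
            if not desc[j, k]:
                continue
            v = P[k] - centre
            cross = np.array([[0, -v[2], v[1]],
                              [v[2], 0, -v[0]],
                              [-v[1], v[0], 0]])
            J_a[k, :, 3 * j:3 * j + 3] = -cross @ A
            if bone_of[j] >= 0:
                J_l[k, :, bone_of[j]] = G[j] @ skeleton.rest_directions[j]
    return J_a, J_l, J_t
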