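"""Build the default mouse skeleton and pose it by forward kinematics.

The skeleton is an 18-joint tree (54 rotational degrees of freedom) with
17 bones; the two ears are derived head markers, completing the 20-point
annotation set.  Forward kinematics maps joint angles (axis-angle per
joint, composed down the chain) and bone lengths to 3D keypoints.
"""

import numpy as np

import mouselift as ml
from mouselift.synthetic import sample_pose

skeleton = ml.build_default_mouse_skeleton()
print(f"joints: {skeleton.n_joints}, angle DOF: {ml.count_dof(skeleton)}, "
      f"keypoints: {len(skeleton.keypoint_names)}")

# a mid-swing gait pose of a cohort-sampled animal, pelvis 30 mm above floor
pose = sample_pose(skeleton, mode="gait", phase=np.pi / 3, seed=0)
pose.root_translation = np.array([0.0, 0.0, 30.0])
keypoints = ml.forward_kinematics(skeleton, pose)

print("\n3D keypoints (mm):")
for name in ("nose", "lower_spine", "left_ankle", "right_ankle", "tail_tip"):
    x, y, z = keypoints.get(name)
    print(f"  {name:12s} ({x:7.1f}, {y:7.1f}, {z:7.1f})")

# bone lengths read back off the 3D positions equal the pose's lengths:
# rotations never stretch a rigid chain
lengths = ml.bone_lengths_from_keypoints(skeleton, keypoints)
print(f"\nmax |measured - true| bone length: "
      f"{np.abs(lengths - pose.bone_lengths).max():.2e} mm "
      f"(lengths are conserved by rotation)")
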