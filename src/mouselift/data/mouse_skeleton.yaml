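# Default laboratory-mouse kinematic chain.
#
# 18 spherical joints in a tree rooted at the pelvis (lower_spine); the two
# ear keypoints are derived markers attached to the head segment, not chain
# joints.  Rest pose: spine along the x-axis (nose toward -x, tail toward +x,
# so the upper_spine -> middle_spine vector is +x, the canonical pose frame),
# dorsal side up (+z), limbs splayed 45 degrees downward.  rest_direction is
# the unit vector from
# the parent joint to this joint in the parent's frame; default_length is the
# rest bone length in millimetres for an adult animal.
joints:
  - {name: lower_spine,    parent: null}
  - {name: middle_spine,   parent: lower_spine,    rest_direction: [-1.0, 0.0, 0.0], default_length: 15.0}
  - {name: upper_spine,    parent: middle_spine,   rest_direction: [-1.0, 0.0, 0.0], default_length: 15.0}
  - {name: nose,           parent: upper_spine,    rest_direction: [-1.0, 0.0, 0.0], default_length: 25.0}
  - {name: tail_base,      parent: lower_spine,    rest_direction: [1.0, 0.0, 0.0],  default_length: 12.0}
  - {name: tail_tip,       parent: tail_base,      rest_direction: [1.0, 0.0, 0.0],  default_length: 60.0}
  - {name: left_shoulder,  parent: upper_spine,    rest_direction: [0.0, 0.7071067811865475, -0.7071067811865475],  default_length: 10.0}
  - {name: left_elbow,     parent: left_shoulder,  rest_direction: [-0.2873478855663454, 0.0, -0.9578262852211513], default_length: 12.0}
  - {name: left_wrist,     parent: left_elbow,     rest_direction: [0.2873478855663454, 0.0, -0.9578262852211513],  default_length: 10.0}
  - {name: right_shoulder, parent: upper_spine,    rest_direction: [0.0, -0.7071067811865475, -0.7071067811865475], default_length: 10.0}
  - {name: right_elbow,    parent: right_shoulder, rest_direction: [-0.2873478855663454, 0.0, -0.9578262852211513], default_length: 12.0}
  - {name: right_wrist,    parent: right_elbow,    rest_direction: [0.2873478855663454, 0.0, -0.9578262852211513],  default_length: 10.0}
  - {name: left_hip,       parent: lower_spine,    rest_direction: [0.0, 0.7071067811865475, -0.7071067811865475],  default_length: 8.0}
  - {name: left_knee,      parent: left_hip,       rest_direction: [-0.2873478855663454, 0.0, -0.9578262852211513], default_length: 15.0}
  - {name: left_ankle,     parent: left_knee,      rest_direction: [0.2873478855663454, 0.0, -0.9578262852211513],  default_length: 15.0}
  - {name: right_hip,      parent: lower_spine,    rest_direction: [0.0, -0.7071067811865475, -0.7071067811865475], default_length: 8.0}
  - {name: right_knee,     parent: right_hip,      rest_direction: [-0.2873478855663454, 0.0, -0.9578262852211513], default_length: 15.0}
  - {name: right_ankle,    parent: right_knee,     rest_direction: [0.2873478855663454, 0.0, -0.9578262852211513],  default_length: 15.0}

# Ear markers: fixed offsets in the head (nose-joint) frame, expressed as a
# fraction of the nose bone length, anchored at the nose keypoint.
ear_markers:
  left_ear:  {anchor: nose, offset: [0.35, 0.35, 0.25]}
  right_ear: {anchor: nose, offset: [0.35, -0.35, 0.25]}
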