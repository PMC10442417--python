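import warnings

import numpy as np
import pytest

import mouselift as ml
from mouselift.synthetic import (default_rig, sample_cohort_bone_lengths,
                                 sample_pose_collection)

warnings.filterwarnings("ignore", message="near-zero-variance")


@pytest.fixture(scope="session")
def skeleton():
    return ml.build_default_mouse_skeleton()


@pytest.fixture(scope="session")
def rig():
    return default_rig()


@pytest.fixture(scope="session")
def top_camera(rig):
    return rig[0]


@pytest.fixture(scope="session")
def cohort_table(skeleton):
    return sample_cohort_bone_lengths(80, 4, seed=3, skeleton=skeleton)


@pytest.fixture(scope="session")
def shape_prior(cohort_table):
    return ml.fit_shape_prior(cohort_table, seed=4)


@pytest.fixture(scope="session")
def pose_prior(skeleton):
    poses = sample_pose_collection(skeleton, 200, seed=1)
    return ml.fit_pose_prior(poses, seed=2)


@pytest.fixture
def toy_chain():
    """Two-joint chain: root plus one child along +x."""
    return ml.SkeletonDefinition(
        joint_names=("root", "tip"),
        parent_index=np.array([-1, 0]),
        rest_directions=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
        keypoint_names=("root", "tip"),
        marker_offsets={},
        default_bone_lengths=np.array([10.0]),
    )
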