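import numpy as np
import pytest

from navactor.belief_filter import BeliefState, initialize_landmark
from navactor.env_model import (
    FieldOfView,
    MotorNoise,
    Observation,
    ObservationNoise,
    WorldState,
)
from navactor.params import NoiseParams
from navactor.belief_filter import RepresentationNoise


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_world():
    """Agent at origin facing east, one landmark ahead and one to the left."""
    return WorldState(0.0, 0.0, 0.0, map=[[5.0, 0.0], [0.0, 4.0]])


@pytest.fixture
def small_noise():
    return NoiseParams(
        motor=MotorNoise(0.05, 0.01, 0.01, 0.05),
        observation=ObservationNoise(0.02, 0.04, 0.02, 0.04),
        representation=RepresentationNoise(0.001),
    )


@pytest.fixture
def zero_noise():
    return NoiseParams.zero()


def make_belief_with_landmarks(pose, landmarks, obs_noise=None, pose_cov=1e-4):
    """Belief with every landmark initialized from a noiseless observation."""
    obs_noise = obs_noise or ObservationNoise()
    landmarks = np.atleast_2d(landmarks)
    b = BeliefState.initial(np.asarray(pose, float), len(landmarks), pose_cov)
    for lid, (mx, my) in enumerate(landmarks):
        r = np.hypot(mx - pose[0], my - pose[1])
        psi = np.arctan2(my - pose[1], mx - pose[0]) - pose[2]
        b = initialize_landmark(b, Observation(lid, r, psi), obs_noise)
    return b


@pytest.fixture
def fov_half_pi():
    return FieldOfView(half_angle=np.pi / 2)
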