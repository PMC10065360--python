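import numpy as np
import pytest
from hypothesis import settings

import knee4d as k

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


def random_rigid(rng: np.random.Generator, max_angle_deg: float = 180.0,
                 max_trans_mm: float = 100.0) -> k.RigidTransform:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(0.0, max_angle_deg)
    t = rng.uniform(-max_trans_mm, max_trans_mm, 3)
    return k.RigidTransform.from_rotvec(axis * angle, translation=t)


@pytest.fixture(scope="session")
def phantom() -> k.KneePhantom:
    return k.make_knee_phantom(seed=1)


@pytest.fixture(scope="session")
def script() -> k.MotionScript:
    return k.make_motion_script()


@pytest.fixture(scope="session")
def static_frames(phantom) -> dict:
    return k.build_static_frames(phantom.landmarks)


@pytest.fixture(scope="session")
def small_phantom() -> k.KneePhantom:
    """Lower-resolution phantom-like scene for fast registration tests."""
    return k.make_knee_phantom(seed=2)


@pytest.fixture(scope="session")
def small_config() -> k.ExperimentConfig:
    """Scaled-down experiment for fast end-to-end tests.

    Fewer volumes need a gentler flexion arc: chained ICP initialization
    relies on small inter-volume pose steps, so the motion amplitude is
    reduced along with the temporal sampling.
    """
    return k.ExperimentConfig(n_volumes=6, max_flexion_deg=30.0,
                              final_flexion_deg=15.0, n_acquisitions=1,
                              icp=k.ICPParams(sample_points=600))
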