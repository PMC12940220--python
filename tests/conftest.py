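import numpy as np
import pytest

from poseform.catalog import load_exercise
from poseform.synth import SquatSimParams, simulate_squat_stream


@pytest.fixture(scope="session")
def squat_config():
    return load_exercise("barbell_squat")


@pytest.fixture(scope="session")
def clean_squat():
    """Noiseless 5-rep squat stream with its kinematic ground truth."""
    return simulate_squat_stream(SquatSimParams(n_reps=5, seed=0))


@pytest.fixture(scope="session")
def jittered_squat():
    """Same motion with heavy Gaussian landmark jitter (sd 0.02)."""
    return simulate_squat_stream(SquatSimParams(n_reps=5, jitter_sd=0.02, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
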