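import numpy as np
import pytest

from lamegait.config import NoiseConfig
from lamegait.synthgen import (
    calibrate_weight_support,
    default_params,
    synthesize_trial,
)


@pytest.fixture(scope="session")
def walk_params():
    return calibrate_weight_support(default_params("walk"))


@pytest.fixture(scope="session")
def trot_params():
    return calibrate_weight_support(default_params("trot"))


@pytest.fixture(scope="session")
def walk_trial_clean(walk_params):
    """Noise-free 20 s walk trial with exact ground truth."""
    return synthesize_trial(
        walk_params, "baseline", "none", duration=20.0, noise=NoiseConfig.none(), seed=0
    )


@pytest.fixture(scope="session")
def trot_trial_clean(trot_params):
    return synthesize_trial(
        trot_params, "baseline", "none", duration=20.0, noise=NoiseConfig.none(), seed=0
    )


@pytest.fixture(scope="session")
def walk_trial_noisy(walk_params):
    return synthesize_trial(
        walk_params, "baseline", "none", duration=20.0, noise=NoiseConfig(), seed=3
    )
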