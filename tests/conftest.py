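import numpy as np
import pytest

from sysobs.generative import GenerativeParams, NoiseSpec
from sysobs.stimulus import DriverSignal, add_fluctuations, build_scene_signal
from sysobs.workflows import ExperimentConfig


@pytest.fixture
def flat_driver():
    """Zero input over 4 s at 250 Hz."""
    times = np.arange(1000) / 250.0
    return DriverSignal(times=times, values=np.zeros(1000), scene_boundaries=np.empty(0))


@pytest.fixture
def constant_driver():
    """Unit input over 4 s at 250 Hz."""
    times = np.arange(1000) / 250.0
    return DriverSignal(times=times, values=np.ones(1000), scene_boundaries=np.empty(0))


@pytest.fixture
def scene_driver():
    """Structured 8-scene driver with fluctuations (seeded)."""
    boundaries = np.array([0.5, 1.0, 1.4, 1.9, 2.5, 3.0, 3.5])
    scene = build_scene_signal(boundaries, fs=250.0, duration=4.0, seed=11)
    return add_fluctuations(scene, noise_sd=0.1, smooth_width=0.05, seed=12)


@pytest.fixture
def default_params():
    return GenerativeParams(
        a=-1.0, b=1.0, c=1.0, k=1.0, sigma_mu=0.2, sigma_M=0.2, obs_noise_sd=0.05
    )


@pytest.fixture
def quiet():
    return NoiseSpec(mode="none")


@pytest.fixture
def fast_config():
    """Default study conditions with a single seed."""
    return ExperimentConfig(seeds=(1,))
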