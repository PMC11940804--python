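import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from spikeloss import (CountMatrix, Kinematics, ReachConfig, SpikeEvents,
                       TuningModel, generate_kinematics, generate_spikes)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_counts(rng):
    """20 bins x 5 units of Poisson counts with generous rates."""
    return CountMatrix(rng.poisson(3.0, size=(20, 5)), bin_width_s=0.128)


@pytest.fixture(scope="session")
def tiny_session():
    """A short synthetic session (kinematics, events, counts) shared by tests."""
    cfg = ReachConfig(session_length_s=60.0, seed=5)
    kin = generate_kinematics(cfg)
    tuning = TuningModel.random(12, cfg, seed=6)
    ev, counts = generate_spikes(kin, tuning, seed=7)
    return cfg, kin, tuning, ev, counts
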