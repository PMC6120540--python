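import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dscflair.sequence import PowerModel, build_base_train
from dscflair.synth import SynthConfig, synth_b1

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_train():
    """The modelled protocol: 192 pulses, 50 deg constant, 3 ms spacing."""
    return build_base_train()


@pytest.fixture(scope="session")
def short_train():
    """A 24-pulse train for fast optimization tests."""
    return build_base_train(
        n_pulses=24, const_angle=60.0, ramp_length=4, echo_spacing=3e-3,
        TR=4.0, TI=1.0, center_echo_index=12,
    )


@pytest.fixture(scope="session")
def power_model():
    return PowerModel()


@pytest.fixture(scope="session")
def subject():
    """Default synthetic 8-channel subject (seed 1, 24^3 grid)."""
    return synth_b1(SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_subject():
    """Smaller synthetic subject for optimization-heavy tests."""
    return synth_b1(SynthConfig(seed=1, grid_shape=(16, 16, 16)))
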