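import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from petkin.compartment import TacModel
from petkin.curves import FrameSchedule
from petkin.simulate import InputFunctionSpec, true_input_function
from petkin.validation import observed_input_function

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default_60min()


@pytest.fixture(scope="session")
def dense_input():
    """Noise-free, densely sampled wild-type input function."""
    return true_input_function(InputFunctionSpec.wildtype())


@pytest.fixture(scope="session")
def observed_input():
    """Input reconstructed from the 16-sample blood schedule (noise-free)."""
    return observed_input_function()


@pytest.fixture(scope="session")
def dense_model(dense_input, schedule):
    return TacModel(dense_input, schedule)


@pytest.fixture(scope="session")
def observed_model(observed_input, schedule):
    return TacModel(observed_input, schedule)
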