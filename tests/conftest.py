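import numpy as np
import pytest
from hypothesis import settings

# property tests draw the same examples on every run
settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from myofame.curves import FrameSchedule, InputFunction
from myofame.simulate import make_input_curve


@pytest.fixture(scope="session")
def frames():
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def bolus_input():
    """A representative gamma-variate bolus input over 20 minutes."""
    return make_input_curve(peak_time=0.5, peak_value=100.0, washout=0.1)


@pytest.fixture(scope="session")
def step_input():
    """Unit step input: Cp = 1 kBq/mL for all t in [0, 20] min."""
    return InputFunction(np.array([0.0, 20.0]), np.array([1.0, 1.0]))
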