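import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import opbox

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_spec():
    return opbox.AmplifierSpec.default()


@pytest.fixture(scope="session")
def quiet_spec(default_spec):
    """The default amplifier with noise switched off (deterministic path)."""
    return opbox.AmplifierSpec(
        stages=default_spec.stages, front_gain=default_spec.front_gain,
        cmrr_db=default_spec.cmrr_db,
        input_impedance_ohm=default_spec.input_impedance_ohm,
        noise_rms_uv=0.0, rail_v=default_spec.rail_v, label="quiet")


@pytest.fixture
def rng():
    return np.random.default_rng(20201027)
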