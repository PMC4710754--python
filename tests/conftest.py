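import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import apclamp as ac

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ik1():
    return ac.get_model("ik_model1")


@pytest.fixture(scope="session")
def ik2():
    return ac.get_model("ik_model2")


@pytest.fixture(scope="session")
def ina():
    return ac.get_model("ina")


@pytest.fixture(scope="session")
def param_ap():
    return ac.parametric_ap()


@pytest.fixture(scope="session")
def mech_ap(ina, ik2):
    """Mechanistic MFB-like synthetic AP (the stand-in for a recorded AP)."""
    return ac.simulate_membrane_ap([ina, ik2], stim_amp=30.0)


@pytest.fixture(scope="session")
def mech_clamp_ik2(mech_ap, ik2):
    """AP-clamp of the revised GHK K+ model on the mechanistic AP."""
    g, c = ac.ap_clamp(mech_ap, ik2)
    return g, c


@pytest.fixture()
def worked_segment():
    """The first polyline segment of the digitized AP: (0, -80) -> (0.039, -77.7)."""
    return ac.VoltageWaveform(np.array([0.0, 0.039]), np.array([-80.0, -77.7]))
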