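import pytest

from stskit import MotionScript, simulate_sts


@pytest.fixture(scope="session")
def five_cycle_sim():
    """Default noiseless five-repetition recording with ground truth."""
    return simulate_sts(script=MotionScript())


@pytest.fixture(scope="session")
def lean25_sim():
    """Noiseless recording with a scripted 25-degree peak trunk lean."""
    return simulate_sts(script=MotionScript(peak_trunk_lean_deg=25.0))
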