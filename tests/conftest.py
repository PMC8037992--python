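import numpy as np
import pytest

from mfperg import build_all_schedules, build_geometry, generate_msequence
from mfperg.cohort import RingTemplate, calibrate_ring_template


@pytest.fixture(scope="session")
def mseq10():
    return generate_msequence(10)


@pytest.fixture(scope="session")
def design10(mseq10):
    """Full 36-element dartboard on a short (period 1023) mother sequence."""
    return build_geometry(shift_spacing=28, period=mseq10.period, epoch_states=10)


@pytest.fixture(scope="session")
def schedules10(mseq10, design10):
    return build_all_schedules(mseq10, design10)


@pytest.fixture(scope="session")
def control_ring1_template():
    """Template calibrated to the control-group foveal-ring parameters
    (N1 −0.5 µV @ 27.08 ms, P1 1.24 µV @ 54.58 ms, N2 −1.5 µV @ 75.83 ms)."""
    return calibrate_ring_template((-0.5, 1.24, -1.5), (27.08, 54.58, 75.83))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
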