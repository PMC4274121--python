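import numpy as np
import pytest

from nodalprog.aif import parker_aif
from nodalprog.config import AcquisitionConfig
from nodalprog.phantoms import TissueTruth


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def frame_times(acq):
    return acq.frame_times()


@pytest.fixture(scope="session")
def aif(frame_times):
    return parker_aif(frame_times)


@pytest.fixture()
def small_truth():
    """2x2 single-slice truth at mid-range tissue parameters."""
    shape = (2, 2)
    return TissueTruth(
        ktrans=np.full(shape, 0.49),
        ve=np.full(shape, 0.18),
        vp=np.full(shape, 0.0024),
        t10=np.full(shape, 1000.0),
        adc=np.full(shape, 0.95e-3),
    )
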