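import numpy as np
import pytest
from numpy.random import SeedSequence

from sfemg.config import AcquisitionConfig, QualificationConfig
from sfemg.simulate import FibreGroundTruth, simulate_fibre


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def quiet_acq():
    """Noise-free acquisition for exact-waveform checks."""
    return AcquisitionConfig(noise_rms_uv=0.0)


@pytest.fixture(scope="session")
def qcfg():
    return QualificationConfig()


@pytest.fixture(scope="session")
def clean_recording(acq):
    """One clean fibre recording with moderate jitter, reused across tests."""
    truth = FibreGroundTruth(mean_latency_us=4200.0, jitter_sd_us=30.0, amplitude_uv=300.0)
    return simulate_fibre(truth, acq, SeedSequence([42, 0]))


def assert_frames_equal(a, b):
    import pandas.testing as pdt

    for key in a:
        pdt.assert_frame_equal(a[key], b[key])
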