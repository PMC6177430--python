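import numpy as np
import pytest

from cochlenv import BoltzmannParams, ThreeToneParams


@pytest.fixture(scope="session")
def model_stim():
    """The standard model stimulus: 14.5/15/15.5 kHz, 1 nm, 100 ms plateau."""
    return ThreeToneParams(A=1.0, f1=14_500.0, f_e=500.0, phi=0.0,
                           duration=0.1, ramp=0.0, ramp_shape="none")


@pytest.fixture(scope="session")
def short_stim():
    """A 20-ms plateau (10 envelope periods) for fast unit tests."""
    return ThreeToneParams(A=1.0, f1=14_500.0, f_e=500.0, phi=0.0,
                           duration=0.02, ramp=0.0, ramp_shape="none")


@pytest.fixture(scope="session")
def channel():
    """Standard MET parameters: I_max 2.5 nA, X0 5.5 nm, Z 1.05 pN, 310.15 K."""
    return BoltzmannParams()


def goertzel_amplitude(samples, sample_rate, f):
    """Independent single-frequency projection oracle (peak convention)."""
    n = samples.size
    t = np.arange(n) / sample_rate
    return 2.0 * np.abs(np.sum(samples * np.exp(-2j * np.pi * f * t))) / n
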