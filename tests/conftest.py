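import numpy as np
import pytest

from strgcn.preprocessing import BANDS, EEGRecording
from strgcn.connectivity import CWTConfig, log_freqs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_recording(rng):
    """4-channel, 8-s broadband recording at 256 Hz."""
    fs = 256.0
    t = np.arange(int(8 * fs)) / fs
    data = rng.standard_normal((4, len(t)))
    return EEGRecording(data=data, fs=fs,
                        channel_names=["Fp1", "Fp2", "Cz", "Pz"])


@pytest.fixture
def theta_cfg():
    band = BANDS["theta"]
    return CWTConfig(freqs=log_freqs(band.lo, band.hi, 10))


def random_connected_weights(rng, n):
    """Random symmetric nonnegative weights with zero diagonal."""
    W = rng.uniform(0, 1, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0.0)
    return W
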