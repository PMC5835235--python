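import numpy as np
import pytest

from happe.core import Recording
from happe.montage import builtin_montage


@pytest.fixture(scope="session")
def montage19():
    return builtin_montage("standard19")


@pytest.fixture(scope="session")
def montage128():
    return builtin_montage("generic128")


def pink_noise(rng, n_channels, n_samples, fs, exponent=1.0):
    """Independent 1/f^exponent channels, unit variance."""
    spec = np.fft.rfft(rng.standard_normal((n_channels, n_samples)), axis=1)
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n_samples, axis=1)
    return x / x.std(axis=1, keepdims=True)


@pytest.fixture()
def pink_recording():
    """8-channel, 60-s pink-noise recording at 250 Hz (~10 uV rms)."""
    rng = np.random.default_rng(77)
    fs, n = 250.0, 15000
    data = 10.0 * pink_noise(rng, 8, n, fs)
    return Recording(data, fs, [f"c{i}" for i in range(8)])
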