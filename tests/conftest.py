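import numpy as np
import pytest


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_pair(rng):
    """A plain white pair of series for estimator identity checks."""
    return rng.standard_normal((2, 201))


def brickwall_bandpass(z: np.ndarray, lo: float, hi: float, fs: float) -> np.ndarray:
    """Ideal FFT band-pass used as an independent band-limiting oracle."""
    n = z.shape[-1]
    spec = np.fft.rfft(z)
    f = np.fft.rfftfreq(n, 1 / fs)
    spec[..., (f < lo) | (f > hi)] = 0
    return np.fft.irfft(spec, n=n)
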