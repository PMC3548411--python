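import numpy as np
import pytest

from tremorkit.metrics import PowerSpectrum


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tone(freq, rate=60.0, n=510, amplitude=1.0, phase=0.3):
    t = np.arange(n) / rate
    return amplitude * np.sin(2.0 * np.pi * freq * t + phase)


def random_spectrum(rng, n_bins=None, band=(1.0, 20.0)):
    """A random nonnegative spectrum on a uniform grid inside ``band``."""
    if n_bins is None:
        n_bins = int(rng.integers(5, 40))
    df = (band[1] - band[0]) / n_bins
    freqs = band[0] + df / 2.0 + df * np.arange(n_bins)
    power = rng.gamma(shape=1.0, scale=1.0, size=n_bins)
    power[rng.random(n_bins) < 0.2] = 0.0
    if power.sum() == 0:
        power[int(rng.integers(n_bins))] = 1.0
    return PowerSpectrum(freqs=freqs, power=power, df=df, band=band)


@pytest.fixture
def tone():
    return make_tone


@pytest.fixture
def spectrum_factory(rng):
    return lambda **kw: random_spectrum(rng, **kw)
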