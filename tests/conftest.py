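import numpy as np
import pytest

from brispec import PeakSet, add_noise, build_spectrometer, synth_truth


@pytest.fixture(scope="session")
def spectrometer():
    """The canonical simulated instrument: 120 pixels over 60 GHz."""
    return build_spectrometer()


@pytest.fixture(scope="session")
def peaks():
    """Rayleigh 1e4 / Brillouin 1e3 at +/-10 GHz, all FWHM 1 GHz."""
    return PeakSet()


@pytest.fixture(scope="session")
def truth(peaks, spectrometer):
    return synth_truth(peaks, spectrometer)


@pytest.fixture()
def noisy_snr5(truth):
    return add_noise(truth, snr=5.0, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
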