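import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from snoglyc.glycochem import default_registry
from snoglyc.spectra_io import RunConfig, Spectrum

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


def make_spectrum(peaks, sid="s1", precursor_mz=1000.0, charge=2, rt=600.0,
                  sample="t", precursor_intensity=None):
    mz, inten = zip(*peaks)
    return Spectrum(id=sid, precursor_mz=precursor_mz, charge=charge, rt=rt,
                    mz=np.array(mz, float), intensity=np.array(inten, float),
                    sample=sample, precursor_intensity=precursor_intensity)


@pytest.fixture
def spectrum_factory():
    return make_spectrum
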