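import numpy as np
import pytest

from threephoton import tissue_optics as to


@pytest.fixture(scope="session")
def paper_like_model():
    """Attenuation model at the measured cortex values."""
    w0 = to.w0_from_three_photon_fwhm(0.45)
    return to.AttenuationModel(extinction_length=270.3, threshold_fluence=1.04, w0=w0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
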