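import numpy as np
import pytest

from otokit import synth


@pytest.fixture(scope="session")
def wt_series_8k():
    """Noise-free control series at 8 kHz with default peak parameters."""
    params = synth.default_abr_params(8000.0, attenuation_db=0.0, noise_sd_uv=0.0, seed=7)
    return synth.simulate_abr_series(params)


@pytest.fixture(scope="session")
def attenuated_series_8k():
    """Same subject with a 20 dB frequency-flat conductive attenuation."""
    params = synth.default_abr_params(8000.0, attenuation_db=20.0, noise_sd_uv=0.0, seed=7)
    return synth.simulate_abr_series(params, genotype="DS")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
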