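import numpy as np
import pytest

from brixspec import SpectraSet, SynthConfig, generate_spectra


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_cfg():
    """Noise-free, scatter-free simulator: spectra are an exact map of Brix."""
    return SynthConfig(n_samples=40, n_bands=64, noise_sd=0.0,
                       scatter_slope_sd=0.0, scatter_offset_sd=0.0, seed=7)


@pytest.fixture
def clean_set(clean_cfg):
    return generate_spectra(clean_cfg)


@pytest.fixture
def random_spectra(rng):
    """Unstructured random spectra for algebraic (non-recovery) checks."""
    n, p = 12, 40
    wl = np.linspace(400.0, 1000.0, p)
    return SpectraSet(rng.random((n, p)), wl, brix=rng.uniform(7, 13, n))
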