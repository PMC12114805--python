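import numpy as np
import pytest

import specphos as sp


@pytest.fixture(scope="session")
def leaf_set() -> sp.SpectraSet:
    """Default leaf-model spectra: 60 samples, full 325-1075 nm grid."""
    return sp.generate_leaf_model(sp.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def planted_set() -> sp.SpectraSet:
    """Planted-signal spectra with the DSI optimum at (850, 950) nm."""
    return sp.generate_planted(sp.SynthConfig(mode="planted", seed=11))


@pytest.fixture()
def tiny_set() -> sp.SpectraSet:
    """Small deterministic set: 5 samples, 40 bands, linear LPC link."""
    rng = np.random.default_rng(2)
    wl = np.arange(400.0, 440.0)
    lpc = np.linspace(0.06, 0.12, 5)
    refl = 0.3 + 0.02 * rng.random((5, wl.size)) + 0.5 * lpc[:, None]
    return sp.SpectraSet(wavelengths=wl, reflectance=refl, lpc=lpc)
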