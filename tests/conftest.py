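import numpy as np
import pytest

import caroraman as cr
from caroraman import pipeline as pl


@pytest.fixture(scope="session")
def cfg():
    """Default synthetic world (532 nm, 400-3100 cm^-1, default noise)."""
    return cr.SynthConfig()


@pytest.fixture(scope="session")
def clean_cfg(cfg):
    """Noise-free copy of the default world."""
    return cfg.noise_free()


@pytest.fixture(scope="session")
def refs(cfg):
    return {c: cr.make_reference_spectrum(c, cfg) for c in cr.CAROTENOIDS}


@pytest.fixture(scope="session")
def water(cfg):
    return cr.make_reference_spectrum("water", cfg)


@pytest.fixture(scope="session")
def bsa(cfg):
    return cr.make_reference_spectrum("bsa", cfg)


@pytest.fixture(scope="session")
def absorption_models(cfg):
    """Per-carotenoid absorption models at c_ref = 1 mg/mL with the
    default path factors (which are also the generator's)."""
    return {
        c: cr.AbsorptionModel.from_raw_absorbance(
            cr.simulate_absorbance(c, 1.0, cfg), cfg.source_wavelength_nm,
            c_ref=1.0, d1=cfg.d1, d2=cfg.d2,
        )
        for c in cr.CAROTENOIDS
    }


@pytest.fixture(scope="session")
def ref_sum(refs):
    s = refs["beta_carotene"].copy()
    s.intensity = sum(r.intensity for r in refs.values())
    s.meta = {"analyte": "carotenoid_sum"}
    return s


@pytest.fixture(scope="session")
def small_spectrum():
    rng = np.random.default_rng(7)
    axis = np.linspace(400.0, 3100.0, 200)
    return cr.Spectrum(axis, rng.random(200) + 0.5)
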