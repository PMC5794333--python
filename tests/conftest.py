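import numpy as np
import pytest

from osmoquant.references import InternalStandardSpec, default_library
from osmoquant.synthetic_data import (
    ImageSimConfig,
    SpectrumSimConfig,
    simulate_ion_image,
    simulate_spectrum,
)


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def standard():
    # comparable in magnitude to the simulated solutes so area ratios are O(1)
    return InternalStandardSpec(concentration=0.05)


@pytest.fixture(scope="session")
def clean_cfg():
    return SpectrumSimConfig(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def mixture_spectrum(library, standard, clean_cfg):
    """Noise-free GB + Ect + TMSP spectrum with known concentrations."""
    conc = {"GB": 0.05, "Ect": 0.02}
    spec = simulate_spectrum(conc, standard.concentration, library, clean_cfg,
                             standard)
    return spec, conc


@pytest.fixture(scope="session")
def clean_image():
    cfg = ImageSimConfig(noise_sd=0.0, seed=0)
    img, truth = simulate_ion_image(cfg)
    return img, truth, cfg
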