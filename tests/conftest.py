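import numpy as np
import pytest

from ppixquant.phantoms import ForwardModelParams, generate_design, simulate_dataset
from ppixquant.spectra import WavelengthGrid


@pytest.fixture(scope="session")
def grid():
    return WavelengthGrid.default()


@pytest.fixture(scope="session")
def small_panel():
    """Reduced factorial panel (24 noisy samples) for fast pipeline tests."""
    design = generate_design(il_levels=(1.0, 3.0, 5.0), hb_levels=(0.5, 2.0),
                             ppix_levels=(0.0, 5.0, 10.0, 15.0), replicates=1)
    return simulate_dataset(design, ForwardModelParams(noise=True, seed=11))


@pytest.fixture(scope="session")
def noisy_panel():
    """Full 108-sample noisy panel at the default study conditions."""
    return simulate_dataset(params=ForwardModelParams(noise=True, seed=7))


@pytest.fixture(scope="session")
def clean_panel():
    """Full 108-sample noiseless panel (inverse-crime conditions)."""
    return simulate_dataset(params=ForwardModelParams(noise=False, seed=7))
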