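import numpy as np
import pytest

from decrypte.pipeline import fit_screen
from decrypte.synth import SynthConfig, generate_screen


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_screen():
    """A 3-drug x 300-protein screen with the default study conditions."""
    return generate_screen(SynthConfig(n_drugs=3, n_proteins=300, seed=7))


@pytest.fixture(scope="session")
def small_curves(small_screen):
    """Fitted curve table for the small screen (shared, read-only)."""
    return fit_screen(small_screen.table)


@pytest.fixture(scope="session")
def noiseless_screen():
    """Noise- and missingness-free screen: ratios satisfy the model exactly."""
    return generate_screen(SynthConfig(n_drugs=2, n_proteins=200,
                                       noise_cov=0.0, missing_rate=0.0,
                                       seed=11))
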