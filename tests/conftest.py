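import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ps_truth_clean():
    """Noise-free, artefact-free ps-regime ground truth (shared, read-only)."""
    from cryphot import synthdata

    return synthdata.ps_truth(seed=7, snr=0, with_chirp=False, with_scatter=False)


@pytest.fixture(scope="session")
def ps_matrix_clean(ps_truth_clean):
    from cryphot import synthdata

    return synthdata.generate_regime(ps_truth_clean, "magic")


@pytest.fixture(scope="session")
def species():
    """Preset species spectra on the default grid, as a name->array dict."""
    from cryphot import synthdata

    basis = synthdata.make_species_spectra()
    return {s.name: s.amplitude for s in basis.species}


@pytest.fixture(scope="session")
def grid():
    from cryphot import synthdata

    return synthdata.default_wavelength_grid()


def rng(seed=0):
    return np.random.default_rng(seed)
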