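import numpy as np
import pytest

from ensotel.oni import classify_phases, running_mean3
from ensotel.preprocess import preprocess_cube
from ensotel.synthetic import default_scenario


@pytest.fixture(scope="session")
def recovery_scenario():
    """High signal-to-noise bundled scenario used by the recovery checks."""
    return default_scenario(seed=0, beta_scale=2.0, noise_sd=0.25)


@pytest.fixture(scope="session")
def recovery_index_labels(recovery_scenario):
    idx = running_mean3(recovery_scenario["index"])
    return idx, classify_phases(idx)


@pytest.fixture(scope="session")
def recovery_gpp(recovery_scenario):
    """Preprocessed sun/shade productivity cubes of the recovery scenario."""
    sun = preprocess_cube(recovery_scenario["gpp_sun"][0])
    shade = preprocess_cube(recovery_scenario["gpp_shade"][0])
    return sun, shade


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
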