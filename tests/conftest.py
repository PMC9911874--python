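import numpy as np
import pytest

import leafmech as lm

TISSUES = (
    "petiole_tension",
    "petiole_compression",
    "venation_tension",
    "intercostal_tension",
)


@pytest.fixture(scope="session")
def all_params():
    """The four shipped fitted parameter sets, keyed by tissue/mode."""
    return {name: lm.load_parameters(name) for name in TISSUES}


@pytest.fixture(scope="session")
def petiole(all_params):
    return all_params["petiole_tension"]


@pytest.fixture
def rng():
    return np.random.default_rng(20230127)
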