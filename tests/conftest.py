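import numpy as np
import pytest

from treeline_thermo import ARCHETYPES, generate_forcing


@pytest.fixture(scope="session")
def alpine_year():
    """One generated year of alpine forcing, shared across tests."""
    return generate_forcing(ARCHETYPES["alpine"], 1, seed=42)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(7)
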