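import numpy as np
import pytest

from foldbind.synthetic import jnk1_scenario, p38a_scenario

#: Residues with the clearest exchange features in the helical complex.
CEST_SUBSET = (38, 39, 42, 43, 44, 45, 46, 47, 49, 50)
#: Residues with the largest dispersion amplitudes in the extended complex.
CPMG_SUBSET = (41, 45, 49, 53, 54)


@pytest.fixture
def jnk1():
    return jnk1_scenario(seed=11)


@pytest.fixture
def p38a():
    return p38a_scenario(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
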