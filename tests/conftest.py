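import numpy as np
import pytest

from filatrap import SimulationParams


@pytest.fixture
def params():
    """Reference single-filament parameter set."""
    return SimulationParams(seed=1234)


@pytest.fixture
def params_nf8():
    """Eight-filament bundle in the stiffer trap."""
    return SimulationParams(Nf=8, kappa_T=0.275, seed=1234)


@pytest.fixture
def rng():
    return np.random.default_rng(987)
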