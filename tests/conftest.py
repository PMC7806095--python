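import numpy as np
import pytest

from anttower.params import SimulationParams


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def small_params():
    """A small but nontrivial world: locking, unlocking and attraction on."""
    return SimulationParams(
        L=12, N=30, Pu=0.1, knl=0.2, c=1.0, steps=200, seed=7, sample_interval=50
    )
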