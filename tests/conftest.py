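import numpy as np
import pytest

from csrdelay import RateParameters, SimulationSpec, build_network, strain_presets
from csrdelay.simulate import simulate_ensemble


@pytest.fixture(scope="session")
def params() -> RateParameters:
    return RateParameters()


@pytest.fixture(scope="session")
def presets():
    return strain_presets()


@pytest.fixture(scope="session")
def small_s_rep1_ensemble(params, presets):
    """A small S_REP1 ensemble shared by quick structural tests."""
    net = build_network(presets["S_REP1"], params)
    return simulate_ensemble(net, SimulationSpec(n_cells=40, seed=7))
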