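import numpy as np
import pytest

from osnet import (NeuronParams, StimulusConfig, assign_input_pos,
                   build_topology, build_weight_matrix)


@pytest.fixture(scope="session")
def tiny_weights():
    """A small Dale-compliant network: 24 exc / 6 inh, in-degrees 6/2."""
    topo = build_topology(24, 6, 6, 2, seed=7)
    return build_weight_matrix(topo, j_epsp=0.2, g=4.0)


@pytest.fixture(scope="session")
def tiny_pos():
    return assign_input_pos(30, seed=8)


@pytest.fixture()
def lif():
    return NeuronParams(model="lif", tau_m=20.0, v_th=20.0, v_rest=0.0,
                        tau_ref=2.0)


@pytest.fixture()
def pif():
    return NeuronParams(model="pif", tau_m=np.inf, v_th=20.0, v_rest=0.0,
                        tau_ref=2.0)


@pytest.fixture()
def stim():
    return StimulusConfig()
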