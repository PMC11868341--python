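import numpy as np
import pytest

from adexz import (
    ExtendedAdExParams,
    NeuronState,
    integrate_neuron,
    reference_params,
)


@pytest.fixture(scope="session")
def params() -> ExtendedAdExParams:
    return reference_params()


@pytest.fixture(scope="session")
def exemplar_runs(params):
    """20 s reference runs at the three exemplar impairment levels, from rest."""
    runs = {}
    for Z0 in (-45.0, -40.0, -20.0):
        p = params.replace(Z0=Z0)
        init = NeuronState(V=p.E_L, w=0.0, z=0.0)
        trace, spikes = integrate_neuron(p, 20000.0, dt=0.1, init=init)
        runs[Z0] = (p, trace, spikes)
    return runs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
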