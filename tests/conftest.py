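import numpy as np
import pytest

import grnsim as g


@pytest.fixture(scope="session")
def repressilator_model():
    return g.make_family(g.FamilySpec("repressilator", 3)).compile()


@pytest.fixture(scope="session")
def repressilator_traj(repressilator_model):
    return g.simulate_ode(repressilator_model, (0.0, 6000.0), max_points=6001)


@pytest.fixture(scope="session")
def crisprlator_model():
    c = g.Circuit(default_model="crispri")
    for i in (1, 2, 3):
        c.add_node(f"N{i}")
    c.add_regulation("N1:CRISPRI |- N3")
    c.add_regulation("N2:CRISPRI |- N1")
    c.add_regulation("N3:CRISPRI |- N2")
    c.set_initial("N1", "P", 50.0)
    c.set_initial("N1", "sgRNA", 10.0)
    return c.compile()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
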