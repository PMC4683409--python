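import numpy as np
import pytest

from kirflux import (PermeationDiagram, PoreState, RateParameterSet,
                     SFConfiguration, TransitionEdge, enumerate_cycles,
                     kir2p1_diagram)


def _edge(u, v, label, ion=0, water=0, kplus="none", sense="efflux"):
    return TransitionEdge(from_state=u, to_state=v, rate_label=label, z=0.0,
                          kplus_dependence=kplus, ion_transfer=ion,
                          water_transfer=water, direction_sense=sense)


def make_toy_triangle():
    """A single-loop 3-state diagram with cycle-a-like stoichiometry."""
    states = {
        1: PoreState(1, SFConfiguration.from_string("i-w-i-w"), False),
        2: PoreState(2, SFConfiguration.from_string("i-w-i-w"), True),
        3: PoreState(3, SFConfiguration.from_string("w-i-w-i"), False),
    }
    edges = {}
    for (u, v, lbl, ion, water) in [(1, 2, "k12", 0, 0), (2, 3, "k23", 1, 0),
                                    (3, 1, "k31", 0, 1)]:
        edges[(u, v)] = _edge(u, v, lbl, ion, water)
        edges[(v, u)] = _edge(v, u, lbl[0] + lbl[2] + lbl[1], -ion, -water,
                              sense="influx")
    return PermeationDiagram(states=states, edges=edges, named_cycles={},
                             checksum={})


@pytest.fixture(scope="session")
def diagram():
    return kir2p1_diagram()


@pytest.fixture(scope="session")
def records(diagram):
    return enumerate_cycles(diagram)


@pytest.fixture(scope="session")
def wt_params():
    return RateParameterSet.wild_type()


@pytest.fixture(scope="session")
def mut_params():
    return RateParameterSet.mutant()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def toy_triangle():
    return make_toy_triangle()


def random_rate_set(rng, low=6.0, high=9.0):
    """Log-uniform random free rates, a generic thermodynamically
    consistent parameter point on the Kir2.1 diagram."""
    return RateParameterSet(
        k0={f"k{i}": float(10 ** rng.uniform(low, high)) for i in range(1, 11)})
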