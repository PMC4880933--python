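import numpy as np
import pytest

from dpdcoat.builders import make_fixture
from dpdcoat.pipeline import build_system, make_engine


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_fluid_engine():
    """A 500-bead pure DPD fluid, cheap to propagate (shared, read-mostly)."""
    sc = make_fixture("pure_fluid", seed=7)
    sc.box = (5.5, 5.5, 5.5)
    topo = build_system(sc, 7)
    return make_engine(sc, topology=topo, seed=7)


def fresh_fluid_engine(seed=7, box=(5.5, 5.5, 5.5)):
    sc = make_fixture("pure_fluid", seed=seed)
    sc.box = box
    topo = build_system(sc, seed)
    return make_engine(sc, topology=topo, seed=seed)
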