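import numpy as np
import pytest

from pacsfit.samplers import EnmMcSampler
from pacsfit.structmodel import Atom, Conformation
from pacsfit.synthetic import make_two_state_toy


@pytest.fixture(scope="session")
def toy_pair():
    """Default two-state hinge system: (closed, open)."""
    return make_two_state_toy()


@pytest.fixture(scope="session")
def sampler():
    return EnmMcSampler()


def make_bead_chain(coords, name="CA"):
    """Build a Cα-bead conformation from raw coordinates."""
    coords = np.asarray(coords, dtype=float)
    atoms = [
        Atom(name=name, residue_number=i + 1, residue_name="ALA", chain_id="A",
             element="C")
        for i in range(len(coords))
    ]
    return Conformation(atoms=atoms, coords=coords, id="chain")


@pytest.fixture
def bead_chain_factory():
    return make_bead_chain
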