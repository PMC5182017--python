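import numpy as np
import pytest

from dloss.structures import Atom, Structure, UnitCell
from dloss.synthetic import DamageScenario, make_damage_series, make_toy_structure


def make_atom(serial=1, name="CA", resname="GLY", resnum=1, element="C",
              pos=(0.0, 0.0, 0.0), occ=1.0, b=10.0, chain="A", altloc=""):
    return Atom(serial=serial, name=name, altloc=altloc, residue_name=resname,
                chain_id=chain, residue_number=resnum, element=element,
                position=np.asarray(pos, dtype=float), occupancy=occ, b_factor=b)


@pytest.fixture(scope="session")
def cubic_cell():
    return UnitCell(20.0, 20.0, 20.0)


@pytest.fixture(scope="session")
def toy_structure():
    return make_toy_structure(2, seed=42)


@pytest.fixture(scope="session")
def decarb_series(toy_structure):
    """Noise-free decarboxylation scenario: Glu oxygens lose 0.2/step."""
    from dloss.structures import AtomTypeKey
    scenario = DamageScenario(
        target_spec={AtomTypeKey("GLU", "OE1"): 0.2,
                     AtomTypeKey("GLU", "OE2"): 0.2},
        noise_sigma=0.0, seed=42)
    refl, truth = make_damage_series(toy_structure, scenario)
    return toy_structure, scenario, refl, truth
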