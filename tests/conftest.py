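import numpy as np
import pytest

from complexeval.config import LDDTParams
from complexeval.structio import Atom, Chain, Residue, Structure
from complexeval.synthgen import FixtureSpec, make_complex, make_model

NO_STEREO = LDDTParams(stereo_check=False)


def single_atom_chain(chain_id, xs, component="GLY", atom_name="CA", element="C",
                      entity="E1", kind="protein"):
    """Chain of single-atom residues at positions xs (list of 3-vectors)."""
    residues = [
        Residue(number=i + 1, component_id=component,
                atoms=[Atom(name=atom_name, element=element, position=np.asarray(x, float))])
        for i, x in enumerate(xs)
    ]
    return Chain(chain_id=chain_id, entity_ref=entity, residues=residues, kind=kind)


def rigid_transform(structure, rotation=None, translation=(0.0, 0.0, 0.0)):
    """Apply a rigid transform to every atom (returns a new Structure)."""
    import copy

    out = copy.deepcopy(structure)
    R = np.eye(3) if rotation is None else np.asarray(rotation)
    t = np.asarray(translation, float)
    for chain in out.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.position = R @ atom.position + t
    return out


def random_rotation(rng):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31))).as_matrix()


@pytest.fixture
def homodimer():
    ref, target = make_complex(
        FixtureSpec(seed=11, n_entities=1, copies_per_entity=(2,), chain_length=40)
    )
    return ref, target


@pytest.fixture
def benzene_complex():
    ref, target = make_complex(
        FixtureSpec(seed=7, n_entities=1, copies_per_entity=(1,),
                    chain_length=40, ligands=("c1ccccc1",))
    )
    return ref, target
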