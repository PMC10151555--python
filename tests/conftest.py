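import numpy as np
import pytest
from rdkit import Chem

from argqsar.chem import Atom, Molecule, SurfaceParams, molecule_from_rdkit


def mol_from_smiles(smiles: str, mol_id: str, seed: int = 7) -> Molecule:
    return molecule_from_rdkit(Chem.MolFromSmiles(smiles), mol_id, embed_seed=seed)


@pytest.fixture(scope="session")
def benzene():
    return mol_from_smiles("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def pyridine():
    return mol_from_smiles("c1ccncc1", "pyridine")


@pytest.fixture(scope="session")
def toluene():
    return mol_from_smiles("Cc1ccccc1", "toluene")


@pytest.fixture(scope="session")
def cyclohexane():
    return mol_from_smiles("C1CCCCC1", "cyclohexane")


@pytest.fixture(scope="session")
def methane():
    return mol_from_smiles("C", "methane")


@pytest.fixture(scope="session")
def ethanol():
    return mol_from_smiles("CCO", "ethanol")


@pytest.fixture(scope="session")
def proline():
    return mol_from_smiles("OC(=O)C1CCCN1", "proline")


@pytest.fixture(scope="session")
def fast_surface_params():
    # coarse sampling keeps surface-based tests quick
    return SurfaceParams(sample_points_per_atom=192)


def toy_molecule(coords, elements=None, bonds=(), masses=None, mol_id="toy"):
    """Hand-built Molecule without any toolkit backing."""
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    elements = elements or ["C"] * n
    masses = masses or [12.0] * n
    atoms = [
        Atom(index=i, element=elements[i], coords=coords[i], mass=masses[i])
        for i in range(n)
    ]
    return Molecule(id=mol_id, atoms=atoms, bonds=[(i, j, 1.0) for i, j in bonds])
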