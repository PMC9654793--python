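import numpy as np
import pytest

from hingedock import Molecule, ParameterSet, assign_atom_types, gasteiger_charges
from hingedock.fixtures import make_toy_complex


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet.default()


@pytest.fixture(scope="session")
def inhibitor2(params) -> Molecule:
    """4-(2-amino-5-phenylpyrimidin-4-yl)benzene-1,3-diol."""
    mol = Molecule.from_smiles(
        "Nc1ncc(-c2ccccc2)c(-c2ccc(O)cc2O)n1", name="inhibitor-2"
    )
    assign_atom_types(mol, params)
    gasteiger_charges(mol)
    return mol


@pytest.fixture(scope="session")
def toy_binder(params):
    return make_toy_complex(1, "binder", params)


@pytest.fixture(scope="session")
def toy_nonbinder(params):
    return make_toy_complex(1, "nonbinder", params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
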