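import numpy as np
import pytest

from peas.chem_core import Atom, Molecule, parse_smiles


@pytest.fixture()
def water() -> Molecule:
    """Hand-built water: O first, bonds perceived by construction."""
    return Molecule(
        name="water",
        atoms=[
            Atom("O", np.array([0.0, 0.0, 0.0])),
            Atom("H", np.array([0.96, 0.0, 0.0])),
            Atom("H", np.array([-0.24, 0.93, 0.0])),
        ],
        bonds=[(0, 1, 1), (0, 2, 1)],
    )


@pytest.fixture(scope="session")
def glycine() -> Molecule:
    return parse_smiles("NCC(=O)O", name="glycine", seed=7)


@pytest.fixture(scope="session")
def butane() -> Molecule:
    return parse_smiles("CCCC", name="butane", seed=7)


@pytest.fixture(scope="session")
def cyclohexane() -> Molecule:
    return parse_smiles("C1CCCCC1", name="cyclohexane", seed=7)


@pytest.fixture(scope="session")
def alkanes() -> dict[int, Molecule]:
    """Linear alkanes keyed by rotatable-bond count (C4..C9 -> ROT 1..6)."""
    return {
        rot: parse_smiles("C" * (rot + 3), name=f"alkane_rot{rot}", seed=7)
        for rot in range(1, 7)
    }
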