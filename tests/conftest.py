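import pytest

from drift.chemio import MoleculeGraph, read_molecule
from drift.synthdata import random_molecule

__all__ = ["random_molecule"]


@pytest.fixture
def ethanol() -> MoleculeGraph:
    return read_molecule("CCO", mol_id="ethanol")


@pytest.fixture
def benzene() -> MoleculeGraph:
    return read_molecule("c1ccccc1", mol_id="benzene")


@pytest.fixture
def toluene() -> MoleculeGraph:
    return read_molecule("Cc1ccccc1", mol_id="toluene")


@pytest.fixture
def caffeine() -> MoleculeGraph:
    return read_molecule("Cn1cnc2c1c(=O)n(C)c(=O)n2C", mol_id="caffeine")


@pytest.fixture
def random_molecules():
    import numpy as np

    rng = np.random.default_rng(1234)
    return [random_molecule(rng, max_atoms=12, mol_id=f"rnd{i}") for i in range(40)]
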