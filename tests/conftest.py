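import numpy as np
import pytest
from rdkit import Chem

from bbbqsar import synthdata


@pytest.fixture(scope="session")
def small_dataset():
    """300-compound synthetic set used by model-level unit tests."""
    records = synthdata.generate_dataset(synthdata.SynthConfig(n_compounds=300, seed=7))
    mols = [Chem.MolFromSmiles(r.structure) for r in records]
    labels = np.array([r.label for r in records], dtype=int)
    return records, mols, labels


@pytest.fixture(scope="session")
def recovery_dataset():
    """The 800-compound seed-7 synthetic set used for parameter recovery."""
    records = synthdata.generate_dataset(synthdata.SynthConfig(n_compounds=800, seed=7))
    mols = [Chem.MolFromSmiles(r.structure) for r in records]
    labels = np.array([r.label for r in records], dtype=int)
    return records, mols, labels


def mol(smiles: str) -> Chem.Mol:
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return m
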