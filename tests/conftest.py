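import pytest
from rdkit import Chem

from vsfunnel.chemio import CompoundLibrary, MoleculeRecord, standardize
from vsfunnel.datasets import query_actives_smiles_synthetic


def record_from_smiles(rec_id: str, smiles: str) -> MoleculeRecord:
    mol = Chem.MolFromSmiles(smiles)
    assert mol is not None, smiles
    return MoleculeRecord(rec_id, mol)


@pytest.fixture(scope="session")
def small_molecules():
    """A handful of well-known small molecules keyed by name."""
    return {
        name: record_from_smiles(name, smi)
        for name, smi in {
            "water": "O",
            "ethane": "CC",
            "ethanol": "CCO",
            "benzene": "c1ccccc1",
            "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
            "sodium_acetate": "CC(=O)[O-].[Na+]",
            "ethylammonium": "CC[NH3+]",
        }.items()
    }


@pytest.fixture(scope="session")
def query_records():
    """Standardized synthetic query actives."""
    return [
        standardize(record_from_smiles(qid, smi))
        for qid, smi in query_actives_smiles_synthetic()
    ]


@pytest.fixture()
def tiny_library(small_molecules):
    recs = [small_molecules[n] for n in ("ethanol", "benzene", "caffeine")]
    return CompoundLibrary(list(recs), provenance="tiny")
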