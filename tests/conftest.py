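import pytest

from fpscreen import (
    FingerprintParams,
    MoleculeRecord,
    SyntheticLibrarySpec,
    build_index,
    generate_library,
    standardize,
)
from fpscreen.synth import DEFAULT_QUERY_SMILES, decoy_source_smiles

THREE_KINDS = ("avalon", "ecfp", "maccs_keys")


def record(smiles: str, mol_id: str = "m") -> MoleculeRecord:
    """A standardized record straight from a SMILES string."""
    return standardize(MoleculeRecord(id=mol_id, smiles_input=smiles, source="test"))


@pytest.fixture(scope="session")
def decoy_corpus() -> list[str]:
    """All curated decoy SMILES (pre-canonicalized in the fixture file)."""
    return [smi for smi, _ in decoy_source_smiles("drugs")]


@pytest.fixture(scope="session")
def query_record() -> MoleculeRecord:
    return record(DEFAULT_QUERY_SMILES, "query")


@pytest.fixture(scope="session")
def standard_fixture() -> list[MoleculeRecord]:
    """The standard benchmark library: 100 decoys + 5 depth-1 analogs, seed 7."""
    return generate_library(SyntheticLibrarySpec(seed=7, n_decoys=100, n_analogs=5))


@pytest.fixture(scope="session")
def three_kind_params() -> list[FingerprintParams]:
    return [FingerprintParams(kind=k) for k in THREE_KINDS]


@pytest.fixture(scope="session")
def standard_index(standard_fixture, three_kind_params):
    return build_index(standard_fixture, three_kind_params)
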