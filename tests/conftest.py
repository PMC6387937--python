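import pytest

from halofrag import FixtureSpec, MoleculeRecord, generate_fixtures


@pytest.fixture(scope="session")
def fixture_pool():
    """The default synthetic fragment set (300 halogenated heteroaryls)."""
    return generate_fixtures(FixtureSpec(seed=0, count=300))


@pytest.fixture(scope="session")
def fixture_200(fixture_pool):
    return fixture_pool[:200]


@pytest.fixture
def make_record():
    def _make(smiles: str, mol_id: str = "M1") -> MoleculeRecord:
        return MoleculeRecord.from_smiles(smiles, mol_id)

    return _make
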