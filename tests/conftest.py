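import pytest

from chemsi.chemio import parse_structure
from chemsi.fixtures import FixtureSpec, SMILES_LIBRARY, build_fixture, library_molecules


@pytest.fixture(scope="session")
def ethanol():
    return parse_structure("CCO", "ethanol")


@pytest.fixture(scope="session")
def benzene():
    return parse_structure("c1ccccc1", "benzene")


@pytest.fixture(scope="session")
def library():
    """All 60 curated library molecules, parsed once per session."""
    return library_molecules()


@pytest.fixture(scope="session")
def fixture_dataset():
    """The seeded 50-compound synthetic dataset (sigma = 0.1, seed 42)."""
    return build_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def benchmark_dataset():
    """A 30-compound benchmark fixture used by the similarity and grid suites."""
    return build_fixture(FixtureSpec(n_molecules=30, seed=42, endpoint_name="bench"))


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny 6-compound dataset for fast read-across unit tests."""
    return build_fixture(FixtureSpec(n_molecules=6, seed=7, endpoint_name="tiny"))


@pytest.fixture(scope="session")
def library_pairs():
    return SMILES_LIBRARY
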