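import pytest

from amesread.fingerprints import fingerprints_for
from amesread.synthetic import FixtureSpec, generate


@pytest.fixture(scope="session")
def small_fixture():
    """Compact congeneric series (8 scaffolds x 8 variants) for fast tests."""
    dataset, descriptors = generate(
        FixtureSpec(n_scaffolds=8, variants_per_scaffold=8, seed=11)
    )
    return dataset, descriptors


@pytest.fixture(scope="session")
def small_fingerprints(small_fixture):
    dataset, _ = small_fixture
    return fingerprints_for({k: k for k in dataset.keys()})


@pytest.fixture(scope="session")
def study_fixture():
    """The 200-compound noise-free series used for parameter recovery."""
    dataset, descriptors = generate(
        FixtureSpec(n_scaffolds=20, variants_per_scaffold=10, seed=42)
    )
    return dataset, descriptors


@pytest.fixture(scope="session")
def study_fingerprints(study_fixture):
    dataset, _ = study_fixture
    return fingerprints_for({k: k for k in dataset.keys()})
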