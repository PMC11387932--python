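import pytest

from amdir import (
    HOST_ASSOCIATED_METAGENOME,
    builtin_schema,
    generate_dataset,
    write_fixture_bundle,
)


@pytest.fixture
def bundle():
    """A mid-sized valid dataset: ~20 samples, 1-3 libraries each."""
    return generate_dataset(20, (1, 3), kind=HOST_ASSOCIATED_METAGENOME, seed=42)


@pytest.fixture(scope="session")
def samples_schema():
    return builtin_schema(HOST_ASSOCIATED_METAGENOME, "samples")


@pytest.fixture(scope="session")
def libraries_schema():
    return builtin_schema(HOST_ASSOCIATED_METAGENOME, "libraries")


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """A bundle written to disk in the recorded-transport layout."""
    d = tmp_path_factory.mktemp("bundle")
    b = generate_dataset(20, (1, 3), kind=HOST_ASSOCIATED_METAGENOME, seed=42)
    write_fixture_bundle(b, d)
    return d
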