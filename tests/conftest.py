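import pytest

from mispscreen.fixtures import (
    FixtureSpec,
    build_toy_taxonomy,
    generate_fixture,
    write_worked_example,
)


@pytest.fixture(scope="session")
def toy_tax():
    return build_toy_taxonomy(shape=(4, 3), seed=11)


@pytest.fixture(scope="session")
def worked_paths(tmp_path_factory):
    """Static worked scenario: dairy peptide ambiguity over synthetic lineages."""
    out = tmp_path_factory.mktemp("worked")
    return write_worked_example(out)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """A seeded synthetic fixture (peptides, offline LCA table, manifest)."""
    out = tmp_path_factory.mktemp("fixture")
    spec = FixtureSpec(seed=7, n_peptides=40)
    return generate_fixture(spec, out)
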