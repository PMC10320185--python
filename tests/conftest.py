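import pytest

from mirenrich.simulate import FixtureSpec, generate_fixture, simulate_fixture


@pytest.fixture(scope="session")
def fixture_data():
    """Seed-1 in-memory fixture shared across tests."""
    return generate_fixture(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Seed-1 fixture written to disk once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    simulate_fixture(FixtureSpec(seed=1), outdir)
    return outdir


@pytest.fixture(scope="session")
def small_spec():
    """Reduced fixture spec for loops that need many seeds."""
    return dict(n_genes=300, n_contexts=2, samples_per_context=2, screen_size=300)
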