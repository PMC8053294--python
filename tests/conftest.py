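import pytest

from diaflux import SimulationConfig, fixture_small, simulate, write_fixture


@pytest.fixture(scope="session")
def fixture_bundle():
    """Hand-built 3-set miniature cohort with exactly known scores."""
    return fixture_small()


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort (10,000 genes, 50 sets, 10 planted)."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture()
def fixture_files(tmp_path):
    """The miniature cohort written as the four standard input files."""
    return write_fixture(tmp_path / "fixture")
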