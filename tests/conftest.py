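import pytest

from sumoscape import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(n_proteins=60, seed=42))


@pytest.fixture(scope="session")
def small_study_dir(small_study, tmp_path_factory):
    """The small study written to disk in all table formats."""
    from sumoscape import write_study

    outdir = tmp_path_factory.mktemp("study")
    paths = write_study(small_study, outdir)
    return paths
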