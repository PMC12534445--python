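import pytest
from hypothesis import settings

from explorindex import SimulationConfig, simulate_dataset, table1_fixture

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def fixture_ds():
    """The deterministic in-study dataset: 67 bouts, 36 individuals."""
    return table1_fixture()


@pytest.fixture()
def sim_ds():
    """One default synthetic dataset with a fixed seed."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def csv_pair(tmp_path):
    """Paths for a bouts/individuals CSV pair in a temp dir."""
    return tmp_path / "bouts.csv", tmp_path / "individuals.csv"
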