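import pytest

from synsel.calibration import SingletonCalibration
from synsel.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic dataset at the default study scale."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def traps_result(default_dataset):
    return SingletonCalibration(default_dataset.variants, transform="sqrt").fit()


@pytest.fixture(scope="session")
def neutral_dataset():
    """A smaller dataset with every planted selection effect zeroed."""
    cfg = SimulationConfig(seed=7, n_genes=80, codons_per_gene=200).neutral()
    return simulate_dataset(cfg)
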