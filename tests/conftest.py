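import pandas as pd
import pytest

from rbprior.synthetic import SimulationConfig, make_truth, simulate_all


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    """One fully simulated input bundle shared across read-only tests."""
    return simulate_all(default_config)


@pytest.fixture(scope="session")
def truth(default_config):
    return make_truth(default_config)


@pytest.fixture()
def toy_calls() -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("s1", "g1", "amplification"),
            ("s1", "g1", "mrna_up"),
            ("s2", "g1", "deep_deletion"),
        ],
        columns=["sample_id", "gene", "category"],
    )
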