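import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from ibmtpath import DEFAULT_COMPARISONS, SimulationConfig, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A small but fully-featured experiment configuration."""
    return SimulationConfig(seed=11, n_probes=2000, n_sets=20, set_size_range=(10, 100))


@pytest.fixture(scope="session")
def small_experiment(small_config):
    """Seeded (study, sets, dag, truth) tuple shared across tests."""
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def paired_comparison():
    """The female 4 h exercised-vs-control contrast (4 subject pairs)."""
    return DEFAULT_COMPARISONS[3]


@pytest.fixture()
def tiny_values():
    return pd.DataFrame(
        np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
        index=pd.Index(["P1", "P2", "P3"], name="probe_id"),
        columns=["s1", "s2"],
    )
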