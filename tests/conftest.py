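import numpy as np
import pytest

from methylbloom.synthetic_data import SimulationConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A small materialized cohort shared by pipeline-level tests."""
    config = SimulationConfig(seed=42, n_accessions=5, n_genes=8, n_causal=3)
    return generate_study(config)


@pytest.fixture
def rng():
    return np.random.default_rng(20240708)
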