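import numpy as np
import pytest

import genopotential as gp


@pytest.fixture(scope="session")
def small_config():
    return gp.SimulationConfig(n_individuals=300, n_markers=40, n_blocks=4,
                               n_causal=20, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return gp.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return gp.preprocess_cohort(small_cohort, seed=7)


@pytest.fixture(scope="session")
def big_cohort():
    """5000-individual cohort used by distributional checks."""
    cfg = gp.SimulationConfig(n_individuals=5000, n_markers=60, n_blocks=6,
                              n_causal=30, seed=11)
    return gp.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_spec():
    return gp.ModelSpec(input_dim=10, embed_dim=8, encoder_dims=(12, 8, 6),
                        planner_hidden=8, action_dim=3, trunk_hidden=6,
                        dropout_p=0.1)


def make_rng(seed=0):
    return np.random.default_rng(seed)
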