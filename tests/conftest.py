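import numpy as np
import pytest

from yieldnet.experiments import make_split
from yieldnet.model import ModelConfig
from yieldnet.synthetic import SimConfig, gen_dataset
from yieldnet.training import TrainConfig, train


@pytest.fixture(scope="session")
def sim_records():
    """A compact synthetic study shared across tests: 30 counties in 5
    states, 2000-2010, default drivers."""
    config = SimConfig(
        n_counties=30, n_states=5, year_start=2000, year_end=2010, seed=7
    )
    records, truth = gen_dataset(config)
    return records, truth


@pytest.fixture(scope="session")
def split(sim_records):
    records, _ = sim_records
    return make_split(records, k=5, val_year=2010)


@pytest.fixture(scope="session")
def small_config():
    return ModelConfig.small(k=5)


@pytest.fixture(scope="session")
def trained(split, small_config):
    """A briefly trained model for tests that need plausible parameters."""
    tconfig = TrainConfig(iterations=600, log_every=200, seed=0)
    params, history = train(
        small_config, split.train_samples, split.val_samples, tconfig
    )
    return params, history
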