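import numpy as np
import pytest

from chilipcnn.data_model import CollectionDesign, Dataset
from chilipcnn.evaluation import run_protocol
from chilipcnn.model import ModelConfig, TrainingConfig
from chilipcnn.synthetic import generate_dataset, make_profile_bank

#: Scaled-down 7-class benchmark design used by the train-in-the-loop tests:
#: same class count and record duration as the full origin-tracing design,
#: fewer bottles/repetitions so a training run takes seconds.
SMALL_DESIGN_7 = CollectionDesign(n_classes=7, n_bottles=4, n_repetitions=3)
BENCHMARK_SEED = 11
BENCHMARK_EPOCHS = 100


@pytest.fixture(scope="session")
def small_design():
    return SMALL_DESIGN_7


@pytest.fixture(scope="session")
def easy_dataset(small_design):
    bank = make_profile_bank(small_design, "easy", seed=BENCHMARK_SEED)
    return generate_dataset(bank, small_design)


@pytest.fixture(scope="session")
def medium_dataset(small_design):
    bank = make_profile_bank(small_design, "medium", seed=BENCHMARK_SEED)
    return generate_dataset(bank, small_design)


@pytest.fixture(scope="session")
def easy_benchmark_run(easy_dataset):
    """Group-2 protocol run on the easy 7-class benchmark (trained once)."""
    config = ModelConfig(n_classes=7)
    tc = TrainingConfig(epochs=BENCHMARK_EPOCHS, seed=BENCHMARK_SEED,
                        n_restarts=3)
    return config, run_protocol(easy_dataset, 2, config, tc)


@pytest.fixture(scope="session")
def medium_group_runs(medium_dataset):
    """Group-1 and group-2 runs on medium difficulty (trained once each)."""
    config = ModelConfig(n_classes=7)
    tc = TrainingConfig(epochs=BENCHMARK_EPOCHS, seed=BENCHMARK_SEED,
                        n_restarts=3)
    g1 = run_protocol(medium_dataset, 1, config, tc)
    g2 = run_protocol(medium_dataset, 2, config, tc)
    return config, g1, g2


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
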