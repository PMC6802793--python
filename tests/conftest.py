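import dataclasses

import numpy as np
import pytest

from gripdisc import GenerativeConfig, calibrate_to_paper, generate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def e1_config():
    return calibrate_to_paper("E1", seed=11)


@pytest.fixture(scope="session")
def e2_config():
    return calibrate_to_paper("E2", seed=12)


@pytest.fixture(scope="session")
def e3_config():
    return calibrate_to_paper("E3", seed=13)


@pytest.fixture(scope="session")
def e1_records(e1_config):
    return generate_experiment(e1_config)


@pytest.fixture(scope="session")
def e3_records(e3_config):
    return generate_experiment(e3_config)


@pytest.fixture(scope="session")
def small_e1_records():
    """A 4-participant, 96-trial session: cheap input for I/O and plumbing tests."""
    cfg = dataclasses.replace(calibrate_to_paper("E1", seed=77), n_participants=4)
    return generate_experiment(cfg)
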