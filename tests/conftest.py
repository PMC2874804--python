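import numpy as np
import pytest
from hypothesis import settings

import driftnet as dn

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pka():
    return dn.PKaTable.default()


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic peptides (20 per charge) with teacher drift times."""
    cfg = dn.SyntheticConfig(n_per_charge={1: 20, 2: 20, 3: 20}, seed=123)
    return dn.generate_dataset(cfg)


@pytest.fixture(scope="session")
def table3():
    return dn.load_table3_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
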