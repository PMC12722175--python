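import numpy as np
import pytest

import nephroref as nr


@pytest.fixture(scope="session")
def toy_tables():
    return nr.make_toy_fixture()


@pytest.fixture(scope="session")
def toy_cohort(toy_tables):
    return nr.build_observations(*toy_tables, horizon_years=5.0)


@pytest.fixture(scope="session")
def sim_tables():
    cfg = nr.SimConfig(n_persons=1500, seed=11)
    return cfg, nr.simulate_cohort(cfg)


@pytest.fixture(scope="session")
def sim_cohort(sim_tables):
    _, tables = sim_tables
    return nr.build_observations(*tables, horizon_years=5.0)


@pytest.fixture(scope="session")
def record_frame():
    """Clean Cox-truth record-level sample with admin censoring at 5y."""
    cfg = nr.SimConfig(n_persons=1, seed=5)
    rec = nr.simulate_record_frame(cfg, 20000, np.random.default_rng(5),
                                   censoring="admin", max_years=5.0)
    return cfg, rec
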