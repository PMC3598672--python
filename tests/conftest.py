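import numpy as np
import pandas as pd
import pytest

from mirblood.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_hc=4, n_asthma=7, n_probes=120, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture()
def toy_counts():
    """Tiny hand-checkable count matrix: 3 endogenous, 2 pos, 2 neg probes."""
    from mirblood.preprocess import CountMatrix

    values = pd.DataFrame(
        {
            "s1": [50.0, 200.0, 10.0, 60.0, 40.0, 0.0, 0.0],
            "s2": [60.0, 300.0, 12.0, 120.0, 80.0, 0.0, 0.0],
        },
        index=["m1", "m2", "m3", "POS_A", "POS_B", "NEG_1", "NEG_2"],
    )
    probe_class = pd.Series(
        ["endogenous"] * 3 + ["pos"] * 2 + ["neg"] * 2, index=values.index
    )
    return CountMatrix(values, probe_class)
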