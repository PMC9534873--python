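import numpy as np
import pandas as pd
import pytest

from c4cn.synth import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_sim():
    """Mid-size cohort under the default generating model, with LD variants."""
    cfg = SimulationConfig(
        n_individuals=10_000,
        seed=20_240_101,
        ld_targets=[
            ("rs_bs_perfect", "bs", 1.0),
            ("rs_bs_08", "bs", 0.8),
            ("rs_null", "AL-BL", 0.0),
        ],
        n_snps=8,
        n_cohorts=2,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def model_b_sim():
    """Large cohort generated under the additive (model-b style) risk model."""
    betas = {"intercept": -0.05, "sex": -1.35, "c4a": -0.31, "c4b": -0.20, "hervk": 0.16}
    cfg = SimulationConfig(n_individuals=25_000, seed=77, risk_betas=betas)
    return simulate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
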