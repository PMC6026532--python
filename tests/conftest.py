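import numpy as np
import pandas as pd
import pytest

from panthoot.simulate import default_config, null_config, simulate_call_table, simulate_focal_days


@pytest.fixture(scope="session")
def default_calls():
    """One default synthetic call table (212 calls, study layout)."""
    return simulate_call_table(default_config(), seed=20_11)


@pytest.fixture(scope="session")
def null_calls():
    """A call table with no predictor effects (type-I regime)."""
    return simulate_call_table(null_config(), seed=20_12)


@pytest.fixture(scope="session")
def default_days():
    """One default synthetic focal-day table (68 days)."""
    return simulate_focal_days(default_config(), seed=20_13)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


@pytest.fixture()
def tiny_calls():
    """Two callers x a handful of calls, fully observed, for toy oracles."""
    cfg = default_config()
    mat = np.zeros((5, 3), dtype=int)
    mat[0] = [1, 1, 1]  # Jacobo
    mat[1] = [1, 1, 1]  # Kuba
    cfg.calls_per_male_per_period = mat
    cfg.missing_prob = {r: 0.0 for r in cfg.missing_prob}
    return simulate_call_table(cfg, seed=5)
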