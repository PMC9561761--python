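import numpy as np
import pandas as pd
import pytest

from pairsig.pairs import build_pairs, filter_pairs, transform
from pairsig.simulate import SimulationConfig, make_toy_fixture, simulate_cohort


@pytest.fixture(scope="session")
def toy_cohort():
    """Deterministic 40-sample / 12-gene cohort with 2 planted pairs."""
    return make_toy_fixture()


@pytest.fixture(scope="session")
def planted_cohort():
    """Mid-size cohort with one strong planted pair (log-HR 1.0)."""
    cfg = SimulationConfig(n_samples=300, n_genes=20, n_true_pairs=1,
                           true_coefficients=[1.0], censoring_rate_target=0.3,
                           seed=1)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def planted_pm(planted_cohort):
    """Filtered pair matrix + clinical table for the planted cohort."""
    expr, clin, truth = planted_cohort
    pm = filter_pairs(transform(expr, build_pairs(list(expr.index))))
    return pm, clin, truth


@pytest.fixture()
def tiny_expr():
    return pd.DataFrame({"S1": [5.0, 3.0, 0.0], "S2": [1.0, 2.0, 0.0]},
                        index=["A", "B", "C"])


@pytest.fixture()
def survival_frame():
    """Small tie-free censored survival table."""
    rng = np.random.default_rng(42)
    n = 80
    t = rng.exponential(20.0, n)
    c = rng.exponential(40.0, n)
    return pd.DataFrame({
        "os_time": np.minimum(t, c),
        "os_event": (t <= c).astype(int),
    }, index=[f"S{i}" for i in range(n)])
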