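import numpy as np
import pandas as pd
import pytest

import turnoverscan as ts


@pytest.fixture(scope="session")
def tree8():
    return ts.make_random_tree(8, seed=42)


@pytest.fixture(scope="session")
def turnover_fixture():
    return ts.read_turnover_table(ts.turnover_fixture_path())


@pytest.fixture(scope="session")
def signal_dataset():
    """Moderate planted-signal dataset shared across tests (read-only)."""
    cfg = ts.SimulationConfig(
        n_tissues=21, n_genes=400, frac_signal=0.05, slope_range=(0.5, 1.0),
        sigma2=0.25, seed=7,
    )
    tree, trait, profiles, matrix, truth = ts.simulate_dataset(cfg)
    return {
        "config": cfg, "tree": tree, "trait": trait,
        "profiles": profiles, "matrix": matrix, "truth": truth,
        "table": ts.TurnoverTable.from_trait(trait),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_pd_cov(rng, n):
    A = rng.normal(size=(n, n))
    return A @ A.T / n + np.eye(n)
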