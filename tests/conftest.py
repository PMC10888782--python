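import numpy as np
import pandas as pd
import pytest

from pollenpipe.synthetic_data import (
    SimulationConfig,
    simulate_methylome_and_tissue_tpm,
    simulate_pollen_experiment,
)


@pytest.fixture(scope="session")
def small_sim():
    """Reduced-scale default experiment shared across unit tests."""
    cfg = SimulationConfig(n_genes=2000, seed=1)
    counts, truth = simulate_pollen_experiment(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def methylome_sim():
    sites, cds, te, tissue_expr, truth = simulate_methylome_and_tissue_tpm(
        n_genes=800, n_mpg=20, seed=3
    )
    return sites, cds, te, tissue_expr, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_counts():
    return pd.DataFrame(
        {"s1": [10, 0, 5], "s2": [20, 0, 10], "s3": [10, 1, 5]},
        index=["gA", "gB", "gC"],
    )
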