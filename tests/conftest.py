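import numpy as np
import pandas as pd
import pytest

from txdamage import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small two-visit cohort with planted effects, shared across tests."""
    cfg = SimulationConfig(n_genes=1000, n_per_group=10, seed=11,
                           frac_de=0.2, length_bias_beta=0.3, cfs_frac=0.1)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def toy_de_table():
    """A hand-written DE table covering both directions and the thresholds."""
    return pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "base_mean": [100.0] * 6,
            "log2fc": [0.35, 0.322, -0.50, -0.40, 1.2, 0.0],
            "se": [0.1] * 6,
            "wald_z": [3.5, 3.2, -5.0, -4.0, 12.0, 0.0],
            "p": [0.001, 0.001, 0.0005, 0.20, 1e-8, 1.0],
            "p_adj": [0.04, 0.001, 0.003, 0.20, 1e-7, 1.0],
        }
    )
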