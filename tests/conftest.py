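import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from evsort.normalize import log_normalize, size_factors
from evsort.simulate import SimConfig, simulate_paired_counts

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """Default-structure simulation at reduced scale, shared across tests."""
    counts, meta, truth = simulate_paired_counts(SimConfig(n_genes=1000, seed=11))
    return counts, meta, truth


@pytest.fixture(scope="session")
def small_norm(small_sim):
    counts, meta, truth = small_sim
    return log_normalize(counts, size_factors(counts))


@pytest.fixture(scope="session")
def module_sim():
    """Module-only simulation (no DE/sorting effects) for network tests."""
    cfg = SimConfig(n_genes=600, frac_location_de=0, frac_sex_de_ev=0,
                    frac_sex_de_cell=0, frac_sorted=0, n_modules=5,
                    module_size=50, seed=0)
    counts, meta, truth = simulate_paired_counts(cfg)
    norm = log_normalize(counts, size_factors(counts))
    return counts, meta, truth, norm


def rand_labels(rng, n, k):
    return pd.Series(rng.integers(0, k, n))


def brute_force_bh(p):
    """Independent step-up implementation used as the BH oracle."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        adj[i] = prev
    return adj
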