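import numpy as np
import pytest

from phenoselect import SimulationConfig, TraitTable, simulate_two_class


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def separable_table():
    """Two well-separated 1-D classes padded with a noise trait."""
    rng = np.random.default_rng(7)
    n = 40
    x1 = np.concatenate([rng.normal(-5, 0.3, n // 2), rng.normal(5, 0.3, n // 2)])
    x2 = rng.normal(0, 1, n)
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    return TraitTable(
        values=np.column_stack([x1, x2]),
        trait_names=["signal", "noise"],
        sample_ids=[f"s{i}" for i in range(n)],
        labels=labels,
    )


@pytest.fixture
def small_sim_table():
    """300 x 25 two-class table from the canonical-size generator."""
    cfg = SimulationConfig(
        n1=150, n2=150, p=25, epsilon=2.25,
        cov_family="compound_symmetry", sigma=1.0, rho=0.2, seed=11,
    )
    return simulate_two_class(cfg)
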