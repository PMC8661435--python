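import numpy as np
import pytest

from rankga import ExpressionMatrix, GAConfig, SimConfig, simulate_trajectory


@pytest.fixture(scope="session")
def small_truth():
    """60-cell, 80-gene no-dropout trajectory shared by read-only tests."""
    return simulate_trajectory(SimConfig(n_cells=60, n_genes=80, dropout_rate=0.0, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_ga():
    """Small GA configuration for tests that only need a decent ordering."""
    return GAConfig(pop_size=40, min_generations=15, max_generations=60, seed=7)


@pytest.fixture
def toy_expr(rng):
    """10 genes x 12 cells of positive values."""
    return ExpressionMatrix(rng.uniform(0.0, 10.0, size=(10, 12)))
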