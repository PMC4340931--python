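import numpy as np
import pytest

from spinet import simulate
from spinet.data_io import ExpressionMatrix, ConditionTable


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expression(rng):
    vals = rng.standard_normal((10, 8))
    return ExpressionMatrix(
        [f"g{i}" for i in range(10)], [f"s{j}" for j in range(8)], vals
    )


@pytest.fixture
def small_conditions(rng):
    vals = np.column_stack(
        [rng.integers(0, 2, 8).astype(float), rng.standard_normal(8)]
    )
    vals[0, 0] = 1.0  # keep the binary column non-constant
    return ConditionTable([f"s{j}" for j in range(8)], ["fed", "rate"], vals)


@pytest.fixture(scope="session")
def default_dataset():
    """Study-shaped synthetic dataset: 1,419 genes x 47 samples, 100 clusters."""
    return simulate.generate(seed=11)
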