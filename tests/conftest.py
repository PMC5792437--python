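import numpy as np
import pandas as pd
import pytest

from cogepipe.io import ExpressionMatrix
from cogepipe.synthetic import SimulationConfig, generate_expression


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """Two lines x three replicates, four genes with known behavior."""
    values = pd.DataFrame(
        {
            "A_r1": [10.0, 1.0, 5.0, 0.0],
            "A_r2": [11.0, 2.0, 5.0, 0.0],
            "A_r3": [9.0, 3.0, 5.0, 0.0],
            "B_r1": [4.0, 4.0, 5.0, 0.0],
            "B_r2": [5.0, 5.0, 5.0, 0.0],
            "B_r3": [6.0, 6.0, 5.0, 0.0],
        },
        index=["down1", "up1", "flat1", "zero1"],
    )
    return ExpressionMatrix(
        values,
        line_order=["A", "B"],
        samples_by_line={"A": ["A_r1", "A_r2", "A_r3"],
                         "B": ["B_r1", "B_r2", "B_r3"]},
    )


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=11)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """One default synthetic dataset shared by the recovery tests."""
    return generate_expression(default_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
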