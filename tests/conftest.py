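import numpy as np
import pandas as pd
import pytest

from dcornet.io_preprocess import ExpressionDataset
from dcornet.synthetic_data import SimulationConfig, generate_two_condition_expression


@pytest.fixture(scope="session")
def default_sim():
    """Generator defaults (seed 1): 2x50-gene modules, 10 switched pairs."""
    return generate_two_condition_expression(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_dataset(default_sim):
    return default_sim[0]


@pytest.fixture(scope="session")
def default_truth(default_sim):
    return default_sim[1]


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples, fully observed, no degenerate genes."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [4.0, 3.0, 2.0, 1.0], [1.0, 3.0, 2.0, 5.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    condition = pd.Series(["A", "A", "B", "B"], index=values.columns)
    return ExpressionDataset(values, condition)


def pairwise_abs_corr(values: np.ndarray) -> np.ndarray:
    """Off-diagonal |r| entries of a genes x samples matrix."""
    r = np.corrcoef(values)
    iu = np.triu_indices_from(r, k=1)
    return np.abs(r[iu])
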