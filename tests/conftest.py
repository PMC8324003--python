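import numpy as np
import pytest

from aitrlearn.data import Dataset
from aitrlearn.simulate import DGPSpec, draw_dataset


@pytest.fixture(scope="session")
def example1_small():
    """A small Example-1 training sample shared across solver tests."""
    data, po = draw_dataset(DGPSpec(example_id=1, p=5), 200, seed=42)
    return data, po


def random_dataset(rng, n, k, p=3):
    """Tiny random weighted-classification instance for solver checks."""
    X = rng.uniform(-1, 1, size=(n, p))
    A = rng.integers(1, k + 1, size=n)
    y = rng.uniform(0.2, 3.0, size=n)
    prop = np.full(n, 1.0 / k)
    return Dataset(X=X, A=A, y=y, propensity=prop, k=k)
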