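import numpy as np
import pytest

from knnvariants import Dataset, generate_synthetic


@pytest.fixture
def tiny_1d():
    """1-D five-point training set with a clear class boundary."""
    X = np.array([[1.0], [2.0], [3.0], [10.0], [11.0]])
    y = np.array(["A", "A", "B", "B", "B"])
    return X, y


@pytest.fixture
def blobs():
    """Two well-separated 2-D Gaussian blobs, 60 points."""
    return generate_synthetic(n=60, d=2, class_sep=6.0, seed=123, name="blobs")


@pytest.fixture
def overlap():
    """Two overlapping classes — harder, exercises real vote logic."""
    return generate_synthetic(n=120, d=4, class_sep=1.5, seed=7, name="overlap")


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
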