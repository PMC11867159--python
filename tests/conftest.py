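import numpy as np
import pytest

from neutraldiv.fixtures import random_tree_with_lengths


@pytest.fixture
def rng():
    return np.random.default_rng(20250220)


@pytest.fixture
def random_trees():
    """Factory: k random YH-topology trees with exponential edge lengths."""
    def make(k, n, seed=0, mean_length=1.0):
        return [random_tree_with_lengths(n, seed + i, mean_length)
                for i in range(k)]
    return make
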