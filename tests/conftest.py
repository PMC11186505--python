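import numpy as np
import pytest

from otoscreen import synthetic
from otoscreen.types import SignedGeneSet


@pytest.fixture
def planted_matrix():
    """Small expression matrix with 5 up and 5 down planted genes at high
    effect and low noise, plus its design and ground truth."""
    matrix, truth = synthetic.gen_expression(
        n_genes=100, n_per_group=5, n_up=5, n_down=5,
        effect_log2fc=3.0, noise_sd=0.1, seed=1)
    return matrix, synthetic.design_from_columns(matrix), truth


@pytest.fixture
def toy_query():
    return SignedGeneSet(up=frozenset({"A", "B", "C"}), down=frozenset({"D", "E"}))


@pytest.fixture
def rng():
    return np.random.default_rng(20240619)
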