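import numpy as np
import pandas as pd
import pytest

from deepkin import GenotypeMatrix, genotypes_to_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_genotypes():
    """3 samples x 4 variants, no missing calls, all polymorphic."""
    G = np.array(
        [
            [0, 2, 1, 0],
            [1, 2, 0, 1],
            [2, 1, 1, 2],
        ],
        dtype=np.int8,
    )
    return genotypes_to_matrix(G)


@pytest.fixture
def toy_with_missing():
    G = np.array(
        [
            [0, 2, -1, 0],
            [1, 2, 0, 1],
            [2, 1, 1, 2],
        ],
        dtype=np.int8,
    )
    return genotypes_to_matrix(G)


def make_matrix(G):
    return genotypes_to_matrix(np.asarray(G, dtype=np.int8))


@pytest.fixture
def pair_table():
    """Five pairs with hand-set theta and p for filtering tests."""
    return pd.DataFrame(
        {
            "ID1": ["a", "a", "a", "b", "b"],
            "ID2": ["b", "c", "d", "c", "d"],
            "THETA": [0.5, 0.02, 0.26, -0.01, 0.01],
            "P": [1e-20, 0.3, 0.5e-6, 2e-6, 0.5],
        }
    )
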