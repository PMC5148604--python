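import numpy as np
import pandas as pd
import pytest

import longscreen as ls


@pytest.fixture
def three_tip_tree():
    return ls.parse_newick("((a:1,b:1):1,c:2);")


@pytest.fixture(scope="session")
def yule15():
    return ls.gen_tree(15, 1)


@pytest.fixture(scope="session")
def traits15(yule15):
    return ls.gen_traits(yule15, 2)


@pytest.fixture(scope="session")
def bm_chol15(yule15):
    """Cholesky factor of the BM covariance of the 15-tip session tree."""
    labels, tmat, _, _ = yule15.path_matrices()
    return labels, np.linalg.cholesky(tmat + 1e-12 * np.eye(len(labels)))


def simulate_bm_feature(labels, L, rng, scale=0.2, slope=0.0, x=None):
    """One feature value vector with BM-distributed residuals."""
    y = scale * (L @ rng.standard_normal(len(labels)))
    if slope and x is not None:
        y = y + slope * np.asarray(x, dtype=float)
    return pd.Series(y, index=labels)
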