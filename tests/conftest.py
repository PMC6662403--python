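import numpy as np
import pandas as pd
import pytest

from ecospec import BundleConfig, TraitTable, simulate_yule_tree, vcv_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def diet_config():
    return BundleConfig({"diet": [f"diet_{i}" for i in range(1, 10)]})


@pytest.fixture
def two_bundle_table():
    """Four species, two bundles, hand-chosen rows spanning the Gini range."""
    cols = {}
    a = np.array(
        [
            [1, 0, 0, 0],  # one-hot -> corrected Gini 1
            [1, 1, 1, 1],  # even -> 0
            [1, 1, 0, 0],  # corrected 2/3
            [1, 1, 1, 0],  # corrected 1/3
        ]
    )
    b = np.array(
        [
            [1, 1, 0],
            [1, 0, 0],
            [1, 1, 1],
            [0, 1, 1],
        ]
    )
    for j in range(4):
        cols[f"a{j}"] = a[:, j]
    for j in range(3):
        cols[f"b{j}"] = b[:, j]
    values = pd.DataFrame(cols, index=["sp1", "sp2", "sp3", "sp4"])
    return TraitTable(values, {"A": [f"a{j}" for j in range(4)], "B": [f"b{j}" for j in range(3)]})


@pytest.fixture(scope="session")
def yule32():
    tree = simulate_yule_tree(32, seed=321)
    return tree, vcv_matrix(tree)


def gini_bruteforce(x, corrected=False):
    """Independent O(n^2) oracle: the literal pairwise double sum."""
    x = np.asarray(x, dtype=float)
    n = x.size
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += abs(x[i] - x[j])
    g = total / (2 * n * n * x.mean())
    if corrected:
        g *= n / (n - 1)
    return g


def morans_i_bruteforce(x, W):
    """Independent double-loop oracle for Moran's I."""
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    n = x.size
    z = x - x.mean()
    num = 0.0
    s0 = 0.0
    for i in range(n):
        for j in range(n):
            num += W[i, j] * z[i] * z[j]
            s0 += W[i, j]
    return n / s0 * num / float(z @ z)
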