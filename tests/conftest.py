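import numpy as np
import pytest

import prismsurv as ps


@pytest.fixture(scope="session")
def two_leaf_truth():
    return ps.two_leaf_truth(n=600, M=15)


@pytest.fixture(scope="session")
def two_leaf_ds(two_leaf_truth):
    """Moderate-size draw from the canonical 2-leaf moderation design."""
    return ps.simulate(two_leaf_truth, seed=11)


@pytest.fixture(scope="session")
def hprism_cfg():
    return ps.TreeConfig(mode="HPRISM", contextual_variable="w")


@pytest.fixture(scope="session")
def prism_cfg():
    return ps.TreeConfig(mode="PRISM")


@pytest.fixture(scope="session")
def hprism_tree(two_leaf_ds, hprism_cfg):
    return ps.grow(two_leaf_ds, hprism_cfg)


def random_survival_arrays(rng, n, censor_frac=0.3):
    """Small random right-censored sample for oracle comparisons."""
    y = rng.normal(2.0, 1.0, size=n)
    delta = (rng.uniform(size=n) > censor_frac).astype(int)
    if delta.sum() == 0:
        delta[rng.integers(n)] = 1
    return y, delta
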