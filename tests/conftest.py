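import numpy as np
import pytest

from gradsim import connectome as cc
from gradsim import synthetic_cohort as syn


@pytest.fixture(scope="session")
def atlas20():
    return syn.make_atlas(20, seed=7)


@pytest.fixture(scope="session")
def atlas100():
    return syn.make_atlas(100, seed=3)


@pytest.fixture(scope="session")
def sc20(atlas20):
    return syn.make_structural_connectome(atlas20, target_density=0.3, seed=1)


@pytest.fixture(scope="session")
def log_sc20(sc20):
    return cc.log_transform(sc20)


def random_connectome(n, seed, density=0.5):
    """Small random symmetric connectome for toy tests."""
    rng = np.random.default_rng(seed)
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < density
    w[iu[0][mask], iu[1][mask]] = rng.lognormal(1.0, 0.5, mask.sum())
    w = w + w.T
    return cc.Connectome(w, weight_kind="raw_streamline")
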