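import numpy as np
import pytest

import expevo as ev
from expevo.engine import McmcSettings


@pytest.fixture(scope="session")
def tree():
    """The five-taxon study tree (root 11.8 MY, youngest split 5.5 MY)."""
    return ev.fixture_tree()


@pytest.fixture(scope="session")
def delta2(tree):
    return {sp: 0.3 for sp in tree.tips}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def fast_settings():
    """Shortened chain schedule for tests that only need rough posteriors."""
    return McmcSettings(burnin=100, iterations=400, thinning=5, seed=7)


@pytest.fixture(scope="session")
def small_dataset(tree):
    ds, truth = ev.generate_dataset(tree, n_genes=40, seed=11)
    return ds, truth
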