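import numpy as np
import pytest

import larvakin as lk


@pytest.fixture(scope="session")
def fixture_tree():
    """The bundled 11-species tree (synthetic relative-time branch lengths)."""
    return lk.read_newick(lk.fixture_tree_path())


@pytest.fixture(scope="session")
def small_tree():
    return lk.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_smoothed_grid(rng, concentration: float = 1.0) -> lk.ProbabilityGrid:
    """Random strictly positive probability grid in the 40 x 70 geometry."""
    probs = rng.gamma(concentration, 1.0, size=(40, 70)) + 1e-6
    probs /= probs.sum()
    return lk.ProbabilityGrid(
        probs=probs, counts_total=1000, dropped_out_of_range=0, pseudocount=1e-9
    )
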