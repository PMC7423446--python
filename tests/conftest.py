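import numpy as np
import pytest

from airspectra import build_tree, fixture_trees


@pytest.fixture(scope="session")
def fixtures():
    return fixture_trees()


@pytest.fixture
def y_tree(fixtures):
    return fixtures["y_tree"]


@pytest.fixture
def two_level(fixtures):
    return fixtures["two_level"]


def make_random_tree(seed, n_nodes=20):
    """Random rooted tree with shuffled input order and random resistances.

    The root always has exactly one child (a trachea-like root branch);
    every other node attaches to a uniformly chosen earlier non-root node,
    which produces a mix of terminal counts, depths and n-furcations.
    """
    rng = np.random.default_rng(seed)
    parents = [0] + [int(rng.integers(1, i)) for i in range(2, n_nodes)]
    edges = [(p, i) for i, p in enumerate(parents, start=1)]
    perm = rng.permutation(len(edges))
    edges = [edges[k] for k in perm]
    radius = rng.uniform(0.5, 3.0, len(edges))
    length = rng.uniform(3.0, 20.0, len(edges))
    resistance = rng.uniform(0.2, 5.0, len(edges))
    return build_tree(edges, radius, length, resistance=resistance)
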