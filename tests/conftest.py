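import numpy as np
import pytest

from qlineage.simulate import (
    assign_random_probabilities,
    assign_uniform_probabilities,
    build_augmented_lineage_fixture,
)
from qlineage.tree import LineageTree


@pytest.fixture(scope="session")
def augmented_fixture():
    """The worked anomalous-triplet lineage tree (1000 inserted cells)."""
    return build_augmented_lineage_fixture(1000)


@pytest.fixture
def six_leaf_binary():
    """Fixed 6-cell binary lineage tree with uniform edge probabilities."""
    return assign_uniform_probabilities(
        LineageTree.from_nested([[["c1", "c2"], ["c3", "c4"]], ["c5", "c6"]], rooted=True)
    )


@pytest.fixture
def six_leaf_polytomy():
    """6-cell tree with a trifurcating root (one unresolved branching)."""
    return assign_uniform_probabilities(
        LineageTree.from_nested([["c1", "c2"], ["c3", "c4"], ["c5", "c6"]], rooted=True)
    )


def random_rooted_tree(n, rng, resolution=1.0):
    """Random rooted tree with exact random probabilities (test helper)."""
    from qlineage.simulate import random_lineage_tree

    return random_lineage_tree(n, resolution=resolution, rng=rng)


@pytest.fixture
def rng():
    return np.random.default_rng(20231201)
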