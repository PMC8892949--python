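"""Shared fixtures: all test data is generated programmatically."""

import numpy as np
import pytest

from concordscape.phylo_core import Node, PhyloTree
from concordscape import synthetic_data


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study bundle (24 taxa, 200 genes x 300 sites)."""
    return synthetic_data.make_fixture(seed=1)


@pytest.fixture(scope="session")
def balanced_tree_factory():
    """Balanced n-tip trees with uniform edge lengths (trait-test substrate)."""

    def build(n: int, edge: float = 0.15) -> PhyloTree:
        leaves = [Node(label=f"t{i}", length=edge) for i in range(n)]
        while len(leaves) > 1:
            nxt = []
            for i in range(0, len(leaves) - 1, 2):
                p = Node(length=edge)
                p.add_child(leaves[i])
                p.add_child(leaves[i + 1])
                nxt.append(p)
            if len(leaves) % 2:
                nxt.append(leaves[-1])
            leaves = nxt
        root = leaves[0]
        root.length = None
        return PhyloTree(root)

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
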