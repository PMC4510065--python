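import numpy as np
import pytest

from coalgrow.core import GenealogyTree, MutationSet


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_two_clade_tree():
    """Hand-built 5-tip ultrametric genealogy with two dated mutations.

    Topology ((t1,(t2,t3)),(t4,t5)); the branch above the 3-tip clade
    carries mutation A (size 3) and the branch above the (t4,t5) cherry
    carries mutation B (size 2), so the spectrum is (0, 1, 1, 0).  Node ids:
    tips 0..4 = t1..t5, internal 5 = (t2,t3) at height 0.2, 6 = the 3-tip
    clade at 0.5, 7 = (t4,t5) at 0.3, 8 = root at 1.0.
    """
    tree = GenealogyTree(
        parent=np.array([6, 5, 5, 7, 7, 6, 8, 8, -1]),
        height=np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.2, 0.5, 0.3, 1.0]),
        tip_ids=np.arange(5),
        tip_labels=np.arange(1, 6),
    )
    ms = MutationSet(
        tree=tree,
        theta=5.0,
        branch=np.array([6, 7]),       # A above node 6, B above node 7
        height=np.array([0.7, 0.6]),
        position=np.array([0.25, 0.75]),
        origin=np.zeros(2, dtype=np.int64),
    )
    return tree, ms


@pytest.fixture
def two_clade_tree():
    return make_two_clade_tree()


@pytest.fixture
def two_clade_star_tip():
    """A tip below mutation B: splitting it must promote B from size 2 to 3."""
    return 3  # node id of t4
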