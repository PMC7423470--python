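import numpy as np
import pytest

from fpdemog.distance import DistanceMatrix
from fpdemog.tree import PhyloTree, simulate_phylogeny


@pytest.fixture(scope="session")
def small_tree() -> PhyloTree:
    """((A:1,B:1):1,C:2); — hand-checkable three-tip tree."""
    return PhyloTree.from_newick("((Alpha_a:1,Beta_b:1):1,Gamma_c:2);")


@pytest.fixture(scope="session")
def yule_tree_50() -> PhyloTree:
    return simulate_phylogeny(50, seed=11)


@pytest.fixture()
def toy_distance() -> DistanceMatrix:
    """Focal 'F' at distances 2, 4, 6 from three community members."""
    labels = ("F", "X", "Y", "Z")
    vals = np.array([
        [0.0, 2.0, 4.0, 6.0],
        [2.0, 0.0, 3.0, 5.0],
        [4.0, 3.0, 0.0, 7.0],
        [6.0, 5.0, 7.0, 0.0],
    ])
    return DistanceMatrix(labels, vals)


def brute_force_cophenetic(tree: PhyloTree):
    """Independent all-pairs path-length oracle: sums edge lengths along
    explicit tip->root paths and subtracts twice the shared prefix."""
    dtree = tree.dendropy_tree
    paths = {}
    for leaf in dtree.leaf_node_iter():
        path = []
        node = leaf
        while node.parent_node is not None:
            path.append((id(node), node.edge.length))
            node = node.parent_node
        paths[leaf.taxon.label] = path
    labels = sorted(paths)
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ids_b = {nid for nid, _ in paths[b]}
            shared = None
            dist_a = 0.0
            for nid, ln in paths[a]:
                if nid in ids_b:
                    shared = nid
                    break
                dist_a += ln
            dist_b = 0.0
            for nid, ln in paths[b]:
                if nid == shared:
                    break
                dist_b += ln
            out[(a, b)] = dist_a + dist_b
    return out
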