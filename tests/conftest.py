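import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def bm_covariance(tree):
    """Brownian-motion covariance oracle: V[a, b] = shared root-to-MRCA path.

    Built directly from node depths, independently of the contrasts code.
    Returns (leaf labels, V).
    """
    leaves = list(tree.leaf_node_iter())
    depth = {}
    for nd in tree.preorder_node_iter():
        parent = nd.parent_node
        depth[id(nd)] = (depth[id(parent)] if parent else 0.0) + (nd.edge.length or 0.0)
    ancestors = {}
    for leaf in leaves:
        path, nd = [], leaf
        while nd is not None:
            path.append(id(nd))
            nd = nd.parent_node
        ancestors[id(leaf)] = path
    n = len(leaves)
    V = np.zeros((n, n))
    for i in range(n):
        seti = set(ancestors[id(leaves[i])])
        for j in range(n):
            mrca = next(a for a in ancestors[id(leaves[j])] if a in seti)
            V[i, j] = depth[mrca]
    return [l.taxon.label for l in leaves], V


def gls_slope(tree, x_by_label, y_by_label):
    """GLS slope of y on (1, x) under the BM covariance; the PIC oracle."""
    labels, V = bm_covariance(tree)
    x = np.array([x_by_label[l] for l in labels])
    y = np.array([y_by_label[l] for l in labels])
    X = np.column_stack([np.ones_like(x), x])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return float(beta[1])


@pytest.fixture(scope="session")
def rodent():
    from phyloblot.simulate import rodent_fixture

    return rodent_fixture()


@pytest.fixture(scope="session")
def analysis_subtree(rodent):
    """The 14-taxon analysis subtree (non-reactive + incomplete species dropped)."""
    from phyloblot import phylo
    from phyloblot.simulate import DEFAULT_ANALYSIS_EXCLUSIONS

    traits, tree = rodent
    keep = [s for s in traits["species"] if s not in DEFAULT_ANALYSIS_EXCLUSIONS]
    return phylo.set_equal_branch_lengths(phylo.prune_to_taxa(tree, keep))
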