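import numpy as np
import pytest
import scipy.sparse as sp

import stripefrac as sf

THREE_LEAF_NEWICK = "((A:1,B:1):1,C:2);"


@pytest.fixture
def three_leaf_tree():
    """The hand-workable 3-leaf tree: A and B at depth 1+1, C at depth 2."""
    return sf.parse_newick(THREE_LEAF_NEWICK)


@pytest.fixture
def singleton_table():
    """Samples X={A}, Y={B}, Z={C}: one unit count on one leaf each."""
    counts = sp.csr_matrix(np.eye(3))
    return sf.FeatureTable(np.array(["A", "B", "C"], dtype=object),
                           np.array(["X", "Y", "Z"], dtype=object), counts)


def make_instance(seed, max_leaves=64, max_samples=32,
                  sparsity_range=(0.5, 0.99), depth=50):
    """A random (table, tree) pair in the small-instance test regime."""
    rng = np.random.default_rng(seed)
    n_leaves = int(rng.integers(3, max_leaves + 1))
    n_samples = int(rng.integers(2, max_samples + 1))
    lo, hi = sparsity_range
    target = min(float(rng.uniform(lo, hi)), 1.0 - 1.0 / n_leaves)
    tree = sf.random_tree(n_leaves, seed=seed)
    table, labels = sf.random_table(sf.SimConfig(
        n_leaves=n_leaves, n_samples=n_samples, target_sparsity=target,
        depth=depth, seed=seed))
    return table, tree


ALL_VARIANTS = [
    sf.VariantParams("unweighted"),
    sf.VariantParams("weighted_unnormalized"),
    sf.VariantParams("weighted_normalized"),
    sf.VariantParams("generalized", alpha=0.5),
    sf.VariantParams("variance_adjusted"),
]
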