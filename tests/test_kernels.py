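"""Embedding, per-pair variant kernels, zero maps and bit packing."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import stripefrac as sf
from stripefrac.errors import TreeTableMismatchError, VariantError
from stripefrac.kernels import (
    EmbeddedTable,
    _bit_columns,
    build_zero_maps,
    embed,
    pack_presence_bits,
    pair_distance,
    popcount,
    unpack_presence_bits,
    unweighted_bitpacked,
)

from conftest import ALL_VARIANTS


def _emb(table, tree, mode):
    return embed(table, tree, mode)


class TestEmbed:
    def test_hand_propagation_proportion(self, three_leaf_tree):
        t = sf.FeatureTable(np.array(["A"], dtype=object),
                            np.array(["X"], dtype=object),
                            sp.csr_matrix([[1.0]]))
        e = _emb(t, three_leaf_tree, "proportion")
        np.testing.assert_allclose(e.values[:, 0], [1, 0, 1, 0, 1])

    def test_hand_propagation_presence(self, three_leaf_tree):
        t = sf.FeatureTable(np.array(["A", "C"], dtype=object),
                            np.array(["Z"], dtype=object),
                            sp.csr_matrix([[1.0], [1.0]]))
        e = _emb(t, three_leaf_tree, "presence")
        np.testing.assert_allclose(e.values[:, 0], [1, 0, 1, 1, 1])

    def test_count_mode_root_equals_totals(self):
        table, tree = _random_pair(seed=3)
        e = _emb(table, tree, "count")
        np.testing.assert_allclose(e.values[-1], table.sample_sums())

    def test_proportion_root_is_one(self):
        table, tree = _random_pair(seed=4)
        e = _emb(table, tree, "proportion")
        np.testing.assert_allclose(e.values[-1], 1.0, atol=1e-9)

    def test_empty_sample_column_stays_zero(self, three_leaf_tree):
        t = sf.FeatureTable(np.array(["A"], dtype=object),
                            np.array(["X", "Y"], dtype=object),
                            sp.csr_matrix([[1.0, 0.0]]))
        e = _emb(t, three_leaf_tree, "proportion")
        assert np.all(e.values[:, 1] == 0)

    def test_mass_nondecreasing_child_to_parent(self):
        table, tree = _random_pair(seed=5)
        e = _emb(table, tree, "count")
        for i in range(tree.n_vertices - 1):
            assert np.all(e.values[tree.parent[i]] >= e.values[i] - 1e-12)

    def test_unmapped_feature_errors_and_drop_flag(self, three_leaf_tree):
        t = sf.FeatureTable(np.array(["A", "ZZZ"], dtype=object),
                            np.array(["X"], dtype=object),
                            sp.csr_matrix([[1.0], [1.0]]))
        with pytest.raises(TreeTableMismatchError, match="ZZZ"):
            _emb(t, three_leaf_tree, "count")
        e = embed(t, three_leaf_tree, "count", drop_unmapped=True)
        assert e.values[-1, 0] == 1.0


def _random_pair(seed):
    tree = sf.random_tree(30, seed=seed)
    table, _ = sf.random_table(sf.SimConfig(
        n_leaves=30, n_samples=10, target_sparsity=0.7, depth=40, seed=seed))
    return table, tree


class TestPairDistance:
    def test_hand_unweighted(self, three_leaf_tree, singleton_table):
        e = _emb(singleton_table, three_leaf_tree, "presence")
        b = e.branch_length
        d = pair_distance(e.values[:, 0], e.values[:, 1], b,
                          sf.VariantParams("unweighted"))
        assert d == pytest.approx(2 / 3, abs=1e-15)

    def test_hand_weighted(self, three_leaf_tree, singleton_table):
        e = _emb(singleton_table, three_leaf_tree, "proportion")
        b = e.branch_length
        u, v = e.values[:, 0], e.values[:, 2]  # {A} vs {C}
        d_raw = pair_distance(u, v, b, sf.VariantParams("weighted_unnormalized"))
        d_norm = pair_distance(u, v, b, sf.VariantParams("weighted_normalized"))
        assert d_raw == pytest.approx(4.0, abs=1e-15)
        assert d_norm == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("params", ALL_VARIANTS,
                             ids=lambda p: p.variant)
    def test_identity_and_symmetry(self, params):
        table, tree = _random_pair(seed=11)
        e = _emb(table, tree, sf.kernels.mode_for_variant(params.variant))
        tot = e.sample_totals
        b = e.branch_length
        u, v = e.values[:, 0], e.values[:, 1]
        assert pair_distance(u, u, b, params, (tot[0], tot[0])) == 0.0
        d1 = pair_distance(u, v, b, params, (tot[0], tot[1]))
        d2 = pair_distance(v, u, b, params, (tot[1], tot[0]))
        assert d1 == pytest.approx(d2, abs=1e-15)
        assert d1 >= 0

    def test_both_empty_is_zero_with_warning(self, three_leaf_tree):
        b = three_leaf_tree.branch_length
        z = np.zeros(5)
        with pytest.warns(UserWarning, match="0/0"):
            assert pair_distance(z, z, b, sf.VariantParams("unweighted")) == 0.0

    def test_variance_adjusted_requires_totals(self):
        with pytest.raises(VariantError):
            pair_distance(np.ones(3), np.ones(3), np.ones(3),
                          sf.VariantParams("variance_adjusted"))


class TestZeroMap:
    def test_all_zero_rows_flagged(self, three_leaf_tree):
        t = sf.FeatureTable(np.array(["A"], dtype=object),
                            np.array(["X"], dtype=object),
                            sp.csr_matrix([[1.0]]))
        e = _emb(t, three_leaf_tree, "count")
        zm = build_zero_maps(e, block=2)
        # vertices B (1) and C (3) carry no mass
        assert len(zm.nonzero[1]) == 0 and len(zm.nonzero[3]) == 0
        assert len(zm.nonzero[0]) == 1

    def test_dense_rows_skip_nothing(self):
        table, tree = _random_pair(seed=13)
        e = _emb(table, tree, "count")
        zm = build_zero_maps(e)
        assert len(zm.nonzero[-1]) == e.n_samples  # root row is dense
        assert not zm.block_all_zero[-1]


class TestBitPacking:
    def test_packing_arithmetic_65_samples(self):
        vals = np.ones((3, 65))
        e = EmbeddedTable(values=vals, branch_length=np.zeros(3),
                          mode="presence", sample_ids=np.arange(65),
                          sample_totals=np.ones(65))
        bm = pack_presence_bits(e)
        assert bm.words.shape == (3, 2)
        assert bm.words[0, 1] == 1  # single bit in the tail word
        assert np.all(unpack_presence_bits(bm))

    def test_non_presence_mode_rejected(self):
        e = EmbeddedTable(values=np.ones((2, 2)), branch_length=np.zeros(2),
                          mode="count", sample_ids=np.arange(2),
                          sample_totals=np.ones(2))
        with pytest.raises(VariantError):
            pack_presence_bits(e)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(1, 40), st.integers(1, 130), st.integers(0, 2**31 - 1))
    def test_pack_unpack_roundtrip(self, nv, ns, seed):
        rng = np.random.default_rng(seed)
        bits = rng.random((nv, ns)) < 0.3
        e = EmbeddedTable(values=bits.astype(float),
                          branch_length=np.zeros(nv), mode="presence",
                          sample_ids=np.arange(ns),
                          sample_totals=np.ones(ns))
        bm = pack_presence_bits(e)
        np.testing.assert_array_equal(unpack_presence_bits(bm), bits)
        # tail bits beyond n_samples are zero
        total_bits = popcount(bm.words).sum()
        assert total_bits == bits.sum()

    def test_popcount_matches_python_bit_count(self):
        rng = np.random.default_rng(0)
        words = rng.integers(0, 2**63, size=(5, 4), dtype=np.uint64)
        expect = np.array([[int(w).bit_count() for w in row] for row in words])
        np.testing.assert_array_equal(popcount(words), expect)

    def test_xor_or_popcounts_match_per_sample_sums(self):
        rng = np.random.default_rng(1)
        a = rng.random((20, 70)) < 0.4
        b_ = rng.random((20, 70)) < 0.4
        ea = EmbeddedTable(a.astype(float), np.zeros(20), "presence",
                           np.arange(70), np.ones(70))
        eb = EmbeddedTable(b_.astype(float), np.zeros(20), "presence",
                           np.arange(70), np.ones(70))
        wa, wb = pack_presence_bits(ea).words, pack_presence_bits(eb).words
        np.testing.assert_array_equal(popcount(wa ^ wb).sum(axis=1),
                                      (a ^ b_).sum(axis=1))
        np.testing.assert_array_equal(popcount(wa | wb).sum(axis=1),
                                      (a | b_).sum(axis=1))


class TestUnweightedBitpacked:
    def test_identical_columns_zero_numerator(self):
        table, tree = _random_pair(seed=17)
        e = _emb(table, tree, "presence")
        bm = pack_presence_bits(e)
        num, den = unweighted_bitpacked(bm, e.branch_length, [(3, 3)])
        assert num[0] == 0.0

    def test_disjoint_singletons_on_star_tree(self):
        tree = sf.parse_newick("(" + ",".join(f"L{i}:1" for i in range(6)) + ");")
        t = sf.FeatureTable(np.array([f"L{i}" for i in range(6)], dtype=object),
                            np.array([f"S{i}" for i in range(6)], dtype=object),
                            sp.csr_matrix(np.eye(6)))
        e = _emb(t, tree, "presence")
        bm = pack_presence_bits(e)
        num, den = unweighted_bitpacked(bm, e.branch_length, [(0, 1)])
        assert num[0] / den[0] == 1.0

    def test_matches_scalar_kernel_exactly(self):
        """100 random pairs agree with the scalar kernel to 0 ulp."""
        tree = sf.random_tree(60, seed=23)
        table, _ = sf.random_table(sf.SimConfig(
            n_leaves=60, n_samples=40, target_sparsity=0.8, depth=30,
            seed=23))
        e = _emb(table, tree, "presence")
        bm = pack_presence_bits(e)
        rng = np.random.default_rng(5)
        pairs = rng.integers(0, 40, size=(100, 2))
        num, den = unweighted_bitpacked(bm, e.branch_length, pairs)
        p = sf.VariantParams("unweighted")
        for t_, (i, j) in enumerate(pairs):
            d = pair_distance(e.values[:, i], e.values[:, j],
                              e.branch_length, p)
            mine = 0.0 if den[t_] == 0 else num[t_] / den[t_]
            assert mine == d  # exact, not approx

    def test_bit_column_extraction(self):
        rng = np.random.default_rng(9)
        bits = rng.random((8, 33)) < 0.5
        e = EmbeddedTable(bits.astype(float), np.zeros(8), "presence",
                          np.arange(33), np.ones(33))
        bm = pack_presence_bits(e)
        cols = _bit_columns(bm, np.arange(33))
        np.testing.assert_array_equal(cols.astype(bool), bits)
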