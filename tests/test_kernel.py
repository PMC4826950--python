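"""ST/SST kernel dynamic program vs the fragment-enumeration oracle."""

import io
import math

import numpy as np
import pytest

from lxre.kernel import (
    DegenerateTreeError,
    FragmentBudgetError,
    GramMatrix,
    KernelConfig,
    delta,
    enumerate_fragments,
    fragment_dot_product,
    gram_matrix,
    kernel_row,
    tree_kernel,
)
from lxre.treebank import read_bracketed

from conftest import grow_random_tree


def raw(variant, decay=1.0):
    return KernelConfig(variant, decay, normalize=False)


class TestDelta:
    def test_matching_preterminals(self, tiny_tree):
        a = tiny_tree.root.children[0]
        assert delta(a, a, raw("SST")) == 1.0
        assert delta(a, a, raw("ST")) == 1.0

    def test_mismatched_preterminals(self, tiny_tree, tiny_tree_variant):
        b1 = tiny_tree.root.children[1]  # (B b)
        b2 = tiny_tree_variant.root.children[1]  # (B c)
        assert delta(b1, b2, raw("SST")) == 0.0

    def test_root_pair_counts_rooted_fragments(self, tiny_tree):
        # SST fragments rooted at S: (S A B), (S (A a) B), (S A (B b)),
        # (S (A a) (B b)); ST: the complete subtree only.
        r = tiny_tree.root
        assert delta(r, r, raw("SST")) == 4.0
        assert delta(r, r, raw("ST")) == 1.0


class TestTreeKernel:
    def test_self_kernel_examples(self, tiny_tree):
        assert tree_kernel(tiny_tree, tiny_tree, raw("ST")) == 3.0
        assert tree_kernel(tiny_tree, tiny_tree, raw("SST")) == 6.0

    def test_cross_kernel_examples(self, tiny_tree, tiny_tree_variant):
        assert tree_kernel(tiny_tree, tiny_tree_variant, raw("ST")) == 1.0
        assert tree_kernel(tiny_tree, tiny_tree_variant, raw("SST")) == 3.0

    @pytest.mark.parametrize("variant", ["ST", "SST"])
    def test_normalized_self_kernel_is_one(self, variant, rng):
        cfg = KernelConfig(variant, 0.7, normalize=True)
        for _ in range(5):
            t = grow_random_tree(rng)
            assert tree_kernel(t, t, cfg) == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["ST", "SST"])
    def test_oracle_equivalence_on_random_pairs(self, variant, rng):
        # decay 1: the DP must equal the fragment-count dot product
        for _ in range(60):
            t1 = grow_random_tree(rng, 5)
            t2 = grow_random_tree(rng, 5)
            expected = fragment_dot_product(t1, t2, variant, budget=5000)
            assert tree_kernel(t1, t2, raw(variant)) == pytest.approx(expected)

    def test_sst_dominates_st_on_self_kernel(self, rng):
        for _ in range(30):
            t = grow_random_tree(rng, 6)
            assert tree_kernel(t, t, raw("SST")) >= tree_kernel(t, t, raw("ST"))

    def test_monotone_in_decay(self, rng):
        for _ in range(10):
            t1, t2 = grow_random_tree(rng), grow_random_tree(rng)
            values = [
                tree_kernel(t1, t2, raw("SST", lam))
                for lam in (0.2, 0.5, 0.8, 1.0)
            ]
            assert all(a <= b + 1e-12 for a, b in zip(values, values[1:]))

    def test_symmetry_is_exact(self, rng):
        for _ in range(10):
            t1, t2 = grow_random_tree(rng), grow_random_tree(rng)
            cfg = raw("SST", 0.5)
            assert tree_kernel(t1, t2, cfg) == tree_kernel(t2, t1, cfg)

    def test_deep_tree_does_not_overflow(self):
        # right-branching chain of height ~300
        text = "(A a)"
        for _ in range(300):
            text = f"(S (A a) {text})"
        [t] = read_bracketed(text)
        cfg = KernelConfig("SST", 0.9, normalize=True)
        assert tree_kernel(t, t, cfg) == pytest.approx(1.0)


class TestEnumerateFragments:
    def test_counts_on_tiny_tree(self, tiny_tree):
        assert sum(enumerate_fragments(tiny_tree, "ST").values()) == 3
        assert sum(enumerate_fragments(tiny_tree, "SST").values()) == 6

    def test_single_preterminal(self):
        [t] = read_bracketed("(A a)")
        assert enumerate_fragments(t, "ST") == {"(A a)": 1}
        assert enumerate_fragments(t, "SST") == {"(A a)": 1}

    def test_budget_guard(self):
        # a wide flat tree has combinatorially many SST fragments
        wide = "(S " + " ".join(f"(A{i} (B{i} b))" for i in range(12)) + ")"
        [t] = read_bracketed(wide)
        with pytest.raises(FragmentBudgetError):
            enumerate_fragments(t, "SST", budget=200)

    def test_duplicate_fragments_counted_with_multiplicity(self):
        [t] = read_bracketed("(S (A a) (A a))")
        frags = enumerate_fragments(t, "ST")
        assert frags["(A a)"] == 2
        # kernel counts occurrence pairs: the two (A a) subtrees match
        # in 4 ways, plus the root pair
        assert tree_kernel(t, t, raw("ST")) == 5.0
        assert fragment_dot_product(t, t, "ST") == 5


class TestGramMatrix:
    def test_entries_match_pairwise_kernel(self, rng):
        trees = [grow_random_tree(rng) for _ in range(6)]
        trees = [type(t)(str(i), t.root) for i, t in enumerate(trees)]
        cfg = raw("SST", 0.6)
        g = gram_matrix(trees, cfg)
        for i in range(6):
            for j in range(6):
                assert g.values[i, j] == pytest.approx(
                    tree_kernel(trees[i], trees[j], cfg)
                )

    def test_symmetric_and_psd(self, rng):
        trees = [grow_random_tree(rng) for _ in range(20)]
        trees = [type(t)(str(i), t.root) for i, t in enumerate(trees)]
        for normalize in (False, True):
            g = gram_matrix(trees, KernelConfig("SST", 0.5, normalize))
            assert np.array_equal(g.values, g.values.T)
            assert np.linalg.eigvalsh(g.values).min() >= -1e-8

    def test_normalized_diagonal_and_range(self, rng):
        trees = [grow_random_tree(rng) for _ in range(8)]
        trees = [type(t)(str(i), t.root) for i, t in enumerate(trees)]
        g = gram_matrix(trees, KernelConfig("ST", 1.0, True))
        assert np.allclose(np.diag(g.values), 1.0, atol=1e-9)
        assert g.values.min() >= -1e-12 and g.values.max() <= 1.0 + 1e-9

    def test_tsv_round_trip(self, rng):
        trees = [grow_random_tree(rng) for _ in range(5)]
        trees = [type(t)(f"id{i}", t.root) for i, t in enumerate(trees)]
        g = gram_matrix(trees, KernelConfig("SST", 0.4, True))
        buf = io.StringIO()
        g.to_tsv(buf)
        g2 = GramMatrix.from_tsv(buf.getvalue())
        assert g2.ids == g.ids
        assert np.abs(g2.values - g.values).max() < 1e-9

    def test_kernel_row_matches_gram_column(self, rng):
        trees = [grow_random_tree(rng) for _ in range(6)]
        trees = [type(t)(str(i), t.root) for i, t in enumerate(trees)]
        cfg = KernelConfig("SST", 0.4, True)
        g = gram_matrix(trees, cfg)
        row = kernel_row(trees[2], trees, cfg)
        assert np.allclose(row, g.values[2], atol=1e-9)


class TestConfigValidation:
    @pytest.mark.parametrize("decay", [0.0, -0.5, 1.5])
    def test_decay_out_of_range(self, decay):
        with pytest.raises(ValueError):
            KernelConfig("SST", decay, True)

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            KernelConfig("PT", 0.5, True)

    def test_delta_rejects_terminals(self, tiny_tree):
        word = tiny_tree.root.children[0].children[0]
        with pytest.raises(DegenerateTreeError):
            delta(word, word, raw("SST"))
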