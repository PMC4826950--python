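"""Shared fixtures: tiny hand-built trees and a random small-tree generator.

The random generator deliberately uses a tiny label alphabet so that
production matches (and even duplicate fragments within one tree) occur
often — the stress case for the kernel dynamic program.
"""

from __future__ import annotations

import numpy as np
import pytest

from lxre.treebank import ParseNode, ParseTree, read_bracketed

_NONTERMINALS = ["S", "A", "B"]
_TERMINALS = ["a", "b"]


def grow_random_tree(rng: np.random.Generator, max_internal: int = 5) -> ParseTree:
    """A random tree with between 1 and ``max_internal`` internal nodes."""
    budget = int(rng.integers(1, max_internal + 1))

    def grow(remaining: list[int]) -> ParseNode:
        label = _NONTERMINALS[rng.integers(len(_NONTERMINALS))]
        n_children = int(rng.integers(1, 4))
        children = []
        for _ in range(n_children):
            if remaining[0] > 0 and rng.random() < 0.6:
                remaining[0] -= 1
                children.append(grow(remaining))
            else:
                children.append(ParseNode(_TERMINALS[rng.integers(len(_TERMINALS))]))
        return ParseNode(label, children)

    budget_box = [budget - 1]  # root consumes one internal node
    return ParseTree("r", grow(budget_box))


@pytest.fixture
def tiny_tree() -> ParseTree:
    return read_bracketed("(S (A a) (B b))")[0]


@pytest.fixture
def tiny_tree_variant() -> ParseTree:
    return read_bracketed("(S (A a) (B c))")[0]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
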