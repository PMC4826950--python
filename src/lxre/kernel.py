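"""Subtree (ST) and subset-tree (SST) convolution kernels.

A convolution tree kernel measures the similarity of two constituency parse
trees as the number of tree fragments they share,

    K(T1, T2) = sum over n1 in N1, n2 in N2 of delta(n1, n2),

where N_i are the internal nodes of T_i and delta(n1, n2) counts the common
fragments rooted at the pair.  The two classical fragment languages are

* **ST** (subtree): a fragment is the *complete* subtree below a node, so
  delta is 1 (times decay) when the subtrees are identical and 0 otherwise;
* **SST** (subset tree, Collins & Duffy): each included node either expands
  its full grammar production or stops, so fragments need not reach the
  leaves.  SST strictly generalizes ST.

Both are computed by one production-matching recursion:

    delta(n1, n2) = 0                        if production(n1) != production(n2)
                  = lam                      if both are preterminals
                  = lam * prod_i  D_i        otherwise, over nonterminal
                                             child pairs, where
                    D_i = 1 + delta(c1_i, c2_i)   (SST)
                    D_i =     delta(c1_i, c2_i)   (ST)

``lam`` is a decay factor in (0, 1] damping the contribution of large
fragments; ``lam = 1`` gives the literal common-fragment count.  The
recursion is evaluated bottom-up over node pairs grouped by production, so
arbitrarily deep trees cannot overflow the interpreter stack.

A brute-force oracle, :func:`enumerate_fragments`, materializes the fragment
multiset of a small tree explicitly; at ``lam = 1`` the kernel equals the dot
product of fragment occurrence counts, which the test suite checks pair by
pair against the dynamic program.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence, TextIO

import numpy as np

from .treebank import ParseNode, ParseTree, serialize_node

__all__ = [
    "KernelConfig",
    "GramMatrix",
    "delta",
    "tree_kernel",
    "enumerate_fragments",
    "gram_matrix",
    "kernel_row",
    "DegenerateTreeError",
    "FragmentBudgetError",
]

Variant = Literal["ST", "SST"]


class DegenerateTreeError(ValueError):
    """A tree with zero internal nodes cannot enter the kernel."""


class FragmentBudgetError(ValueError):
    """Explicit enumeration requested for a tree with too many fragments."""


@dataclass(frozen=True)
class KernelConfig:
    """Fully determines a tree-kernel function.

    Parameters
    ----------
    variant:
        ``"ST"`` or ``"SST"`` fragment language.
    decay:
        Decay factor in (0, 1]; 1.0 reproduces the plain common-fragment
        count.
    normalize:
        If true, kernel values are cosine-normalized,
        ``K(a,b) / sqrt(K(a,a) K(b,b))``, so self-similarity is 1 and trees
        of very different sizes become comparable.
    """

    variant: Variant = "SST"
    decay: float = 1.0
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.variant not in ("ST", "SST"):
            raise ValueError(f"variant must be ST or SST, got {self.variant!r}")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError(f"decay must lie in (0, 1], got {self.decay}")


# ---------------------------------------------------------------------------
# pairwise dynamic program


def _delta_table(
    nodes1: Sequence[ParseNode], nodes2: Sequence[ParseNode], config: KernelConfig
) -> dict[tuple[int, int], float]:
    """delta for every matching internal-node pair, computed bottom-up.

    Node pairs are processed in order of increasing subtree height, so every
    child pair's delta exists before its parents need it — no recursion.
    """
    heights1 = _heights(nodes1)
    heights2 = _heights(nodes2)
    by_prod: dict[object, list[ParseNode]] = {}
    for n in nodes2:
        by_prod.setdefault(n.production(), []).append(n)

    sst = config.variant == "SST"
    lam = config.decay
    table: dict[tuple[int, int], float] = {}
    for n1 in sorted(nodes1, key=lambda n: heights1[id(n)]):
        prod = n1.production()
        for n2 in by_prod.get(prod, ()):
            if n1.is_preterminal:
                table[(id(n1), id(n2))] = lam
                continue
            value = lam
            for c1, c2 in zip(n1.children, n2.children):
                if c1.is_terminal:  # matched via the production; factor 1
                    continue
                d = table.get((id(c1), id(c2)), 0.0)
                value *= (1.0 + d) if sst else d
                if value == 0.0:
                    break
            table[(id(n1), id(n2))] = value
    return table


def _heights(nodes: Iterable[ParseNode]) -> dict[int, int]:
    out: dict[int, int] = {}
    for n in nodes:
        _fill_height(n, out)
    return out


def _fill_height(root: ParseNode, out: dict[int, int]) -> None:
    stack: list[tuple[ParseNode, bool]] = [(root, False)]
    while stack:
        node, seen = stack.pop()
        if id(node) in out:
            continue
        if node.is_terminal:
            out[id(node)] = 0
        elif seen:
            out[id(node)] = 1 + max(out[id(c)] for c in node.children)
        else:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children if id(c) not in out)


def delta(n1: ParseNode, n2: ParseNode, config: KernelConfig) -> float:
    """Number of common fragments rooted at the pair (decay-weighted)."""
    if n1.is_terminal or n2.is_terminal:
        raise DegenerateTreeError("delta is defined on internal nodes only")
    if n1.production() != n2.production():
        return 0.0
    sub1 = [n for n in n1.iter_nodes() if not n.is_terminal]
    sub2 = [n for n in n2.iter_nodes() if not n.is_terminal]
    return _delta_table(sub1, sub2, config).get((id(n1), id(n2)), 0.0)


def _raw_kernel(t1: ParseTree, t2: ParseTree, config: KernelConfig) -> float:
    nodes1 = t1.root.internal_nodes()
    nodes2 = t2.root.internal_nodes()
    if not nodes1 or not nodes2:
        bad = t1 if not nodes1 else t2
        raise DegenerateTreeError(
            f"instance {bad.instance_id!r} has no internal nodes"
        )
    table = _delta_table(nodes1, nodes2, config)
    return float(sum(table.values()))


def tree_kernel(t1: ParseTree, t2: ParseTree, config: KernelConfig) -> float:
    """K(t1, t2): sum of delta over all internal-node pairs.

    With ``config.normalize`` the cosine-normalized value
    ``K(t1,t2)/sqrt(K(t1,t1) K(t2,t2))`` is returned (computed from the
    unnormalized kernel).
    """
    k = _raw_kernel(t1, t2, config)
    if not config.normalize:
        return k
    k11 = _raw_kernel(t1, t1, config)
    k22 = _raw_kernel(t2, t2, config)
    return k / math.sqrt(k11 * k22)


# ---------------------------------------------------------------------------
# brute-force fragment oracle


def enumerate_fragments(
    tree: ParseTree, variant: Variant, budget: int = 200
) -> dict[str, int]:
    """Explicit fragment multiset of a small tree, keyed by canonical string.

    ST: one fragment per internal node — the complete subtree below it.
    SST: every fragment reachable by, at each included nonterminal, either
    expanding its full production and choosing per nonterminal child to stop
    or continue.  Every fragment contains at least one production.

    Intended as an independent oracle for the dynamic program; raises
    :class:`FragmentBudgetError` beyond ``budget`` fragments.
    """
    counts: dict[str, int] = {}
    total = 0
    for node in tree.root.internal_nodes():
        if variant == "ST":
            frags = [serialize_node(node)]
        else:
            frags = _sst_fragments(node, budget + 1)
        total += len(frags)
        if total > budget:
            raise FragmentBudgetError(
                f"fragment count exceeds budget of {budget}"
            )
        for f in frags:
            counts[f] = counts.get(f, 0) + 1
    return counts


def _sst_fragments(node: ParseNode, cap: int) -> list[str]:
    """All SST fragment strings rooted at ``node`` (node expands its production)."""
    options: list[list[str]] = []
    for child in node.children:
        if child.is_terminal:
            options.append([child.label])
        else:
            # stop at the child (bare label) or continue into its fragments
            opts = [child.label] + _sst_fragments(child, cap)
            options.append(opts)
        n = 1
        for o in options:
            n *= len(o)
        if n > cap:
            raise FragmentBudgetError(f"fragment count exceeds budget of {cap - 1}")
    frags: list[str] = []
    stack: list[tuple[int, list[str]]] = [(0, [])]
    while stack:
        i, chosen = stack.pop()
        if i == len(options):
            frags.append(f"({node.label} " + " ".join(chosen) + ")")
            continue
        for opt in options[i]:
            stack.append((i + 1, chosen + [opt]))
    return frags


def fragment_dot_product(
    t1: ParseTree, t2: ParseTree, variant: Variant, budget: int = 200
) -> int:
    """Oracle kernel value at decay 1: sum_f count1(f) * count2(f)."""
    c1 = enumerate_fragments(t1, variant, budget)
    c2 = enumerate_fragments(t2, variant, budget)
    return sum(n * c2[f] for f, n in c1.items() if f in c2)


# ---------------------------------------------------------------------------
# Gram matrices


@dataclass
class GramMatrix:
    """Symmetric matrix of pairwise kernel values keyed by instance ids."""

    ids: list[str]
    values: np.ndarray
    config: KernelConfig | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )

    def index(self, instance_id: str) -> int:
        return self.ids.index(instance_id)

    def submatrix(self, row_ids: Sequence[str], col_ids: Sequence[str]) -> np.ndarray:
        pos = {iid: i for i, iid in enumerate(self.ids)}
        r = [pos[i] for i in row_ids]
        c = [pos[i] for i in col_ids]
        return self.values[np.ix_(r, c)]

    def to_tsv(self, stream: TextIO) -> None:
        """Header row of instance ids, then the square numeric block.

        Values are printed with 17 significant digits so export -> import
        round-trips well within 1e-9.
        """
        stream.write("\t".join(self.ids) + "\n")
        for row in self.values:
            stream.write("\t".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def from_tsv(cls, stream: TextIO | str) -> "GramMatrix":
        if isinstance(stream, str):
            stream = io.StringIO(stream)
        header = stream.readline().rstrip("\n")
        ids = header.split("\t")
        rows = [
            [float(v) for v in line.split("\t")]
            for line in stream
            if line.strip()
        ]
        return cls(ids=ids, values=np.array(rows, dtype=float))


def gram_matrix(trees: Sequence[ParseTree], config: KernelConfig) -> GramMatrix:
    """Pairwise kernel matrix; upper triangle computed, then mirrored.

    Symmetric by construction.  Normalization divides by the square roots of
    the diagonal of the unnormalized matrix, so the normalized diagonal is
    exactly 1.
    """
    if not trees:
        raise ValueError("gram_matrix needs at least one tree")
    n = len(trees)
    raw_cfg = KernelConfig(config.variant, config.decay, normalize=False)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            try:
                values[i, j] = _raw_kernel(trees[i], trees[j], raw_cfg)
            except DegenerateTreeError as exc:
                raise DegenerateTreeError(
                    f"{exc} (while building Gram matrix)"
                ) from None
            values[j, i] = values[i, j]
    if config.normalize:
        d = np.sqrt(np.diag(values))
        values = values / np.outer(d, d)
        np.fill_diagonal(values, 1.0)
    return GramMatrix(ids=[t.instance_id for t in trees], values=values, config=config)


def kernel_row(
    tree: ParseTree, reference_trees: Sequence[ParseTree], config: KernelConfig
) -> np.ndarray:
    """Kernel of one tree against each reference tree (prediction-time rows).

    Uses the same normalization convention as :func:`gram_matrix`.
    """
    raw_cfg = KernelConfig(config.variant, config.decay, normalize=False)
    row = np.array([_raw_kernel(tree, r, raw_cfg) for r in reference_trees])
    if config.normalize:
        k_self = _raw_kernel(tree, tree, raw_cfg)
        refs = np.array([_raw_kernel(r, r, raw_cfg) for r in reference_trees])
        row = row / np.sqrt(k_self * refs)
    return row
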