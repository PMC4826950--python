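"""Constituency parse trees and labeled instance corpora.

Trees are stored in the Penn-Treebank bracketed dialect that statistical
parsers such as the Stanford Parser emit: one balanced ``(LABEL child ...)``
expression per line, with literal parentheses inside tokens escaped as
``-LRB-``/``-RRB-``.  Relation labels (+1 = relation present, -1 = none)
travel in a separate two-column TSV so the tree file stays a pure standard
format.

Labels are case-sensitive and never normalized: the tree kernels downstream
compare node labels by string equality, so any silent normalization would
change kernel values.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence, TextIO

__all__ = [
    "ParseNode",
    "ParseTree",
    "Production",
    "LabeledCorpus",
    "TreebankError",
    "read_bracketed",
    "write_bracketed",
    "productions_of",
    "read_labels",
    "write_labels",
]


class TreebankError(ValueError):
    """Malformed bracketed input or label table."""


@dataclass(frozen=True)
class Production:
    """A grammar production ``parent -> child_labels`` at one internal node.

    Equality is order-sensitive tuple equality: constituency order is
    meaningful, so ``NP -> DT NN`` and ``NP -> NN DT`` are distinct.
    """

    parent: str
    child_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.child_labels:
            raise TreebankError(f"production {self.parent!r} has no children")

    def __str__(self) -> str:
        return f"{self.parent} -> {' '.join(self.child_labels)}"


class ParseNode:
    """A node of a constituency tree: a nonterminal, POS tag, or word.

    A node with no children is a terminal (word); a node whose children are
    all terminals is a preterminal (POS tag over a word).
    """

    __slots__ = ("label", "children")

    def __init__(self, label: str, children: Sequence["ParseNode"] = ()) -> None:
        if not label:
            raise TreebankError("empty node label")
        if any(ch.isspace() for ch in label) or "(" in label or ")" in label:
            raise TreebankError(
                f"label {label!r} contains whitespace or unescaped parentheses"
            )
        self.label = label
        self.children: tuple[ParseNode, ...] = tuple(children)

    @property
    def is_terminal(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return bool(self.children) and all(c.is_terminal for c in self.children)

    def production(self) -> Production:
        if self.is_terminal:
            raise TreebankError("terminal nodes carry no production")
        return Production(self.label, tuple(c.label for c in self.children))

    def iter_nodes(self) -> Iterator["ParseNode"]:
        """Pre-order traversal, iterative so deep trees cannot overflow."""
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def internal_nodes(self) -> list["ParseNode"]:
        return [n for n in self.iter_nodes() if not n.is_terminal]

    def height(self) -> int:
        """Edges on the longest root-to-leaf path (terminal -> 0)."""
        # post-order without recursion
        out: dict[int, int] = {}
        stack: list[tuple[ParseNode, bool]] = [(self, False)]
        while stack:
            node, seen = stack.pop()
            if node.is_terminal:
                out[id(node)] = 0
            elif seen:
                out[id(node)] = 1 + max(out[id(c)] for c in node.children)
            else:
                stack.append((node, True))
                stack.extend((c, False) for c in node.children)
        return out[id(self)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParseNode):
            return NotImplemented
        # iterative structural equality
        stack = [(self, other)]
        while stack:
            a, b = stack.pop()
            if a.label != b.label or len(a.children) != len(b.children):
                return False
            stack.extend(zip(a.children, b.children))
        return True

    def __hash__(self) -> int:  # identity hash: nodes are mutable-free but large
        return object.__hash__(self)

    def __repr__(self) -> str:
        return f"ParseNode({serialize_node(self)!r})"


@dataclass(frozen=True)
class ParseTree:
    """One sentence instance: an id plus the root of its parse."""

    instance_id: str
    root: ParseNode

    def __post_init__(self) -> None:
        if self.root.is_terminal:
            raise TreebankError(
                f"instance {self.instance_id!r}: root must be a nonterminal"
            )

    def __str__(self) -> str:
        return serialize_node(self.root)


@dataclass
class LabeledCorpus:
    """Parse trees plus a (possibly partial) map instance_id -> {+1, -1}."""

    trees: list[ParseTree] = field(default_factory=list)
    labels: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.instance_id for t in self.trees]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TreebankError(f"duplicate instance ids: {dup}")
        missing = set(self.labels) - set(ids)
        if missing:
            raise TreebankError(f"labels refer to unknown ids: {sorted(missing)}")
        bad = {k: v for k, v in self.labels.items() if v not in (+1, -1)}
        if bad:
            raise TreebankError(f"labels must be +1/-1, got {bad}")

    @property
    def ids(self) -> list[str]:
        return [t.instance_id for t in self.trees]

    def tree(self, instance_id: str) -> ParseTree:
        for t in self.trees:
            if t.instance_id == instance_id:
                return t
        raise KeyError(instance_id)

    def subset(self, ids: Iterable[str]) -> "LabeledCorpus":
        wanted = list(ids)
        by_id = {t.instance_id: t for t in self.trees}
        return LabeledCorpus(
            trees=[by_id[i] for i in wanted],
            labels={i: self.labels[i] for i in wanted if i in self.labels},
        )

    def __len__(self) -> int:
        return len(self.trees)


# ---------------------------------------------------------------------------
# bracketed i/o


def _tokenize(line: str) -> Iterator[str]:
    buf: list[str] = []
    for ch in line:
        if ch in "()":
            if buf:
                yield "".join(buf)
                buf.clear()
            yield ch
        elif ch.isspace():
            if buf:
                yield "".join(buf)
                buf.clear()
        else:
            buf.append(ch)
    if buf:
        yield "".join(buf)


def _parse_line(line: str, lineno: int) -> ParseNode:
    tokens = list(_tokenize(line))
    if not tokens:
        raise TreebankError(f"line {lineno}: empty tree")
    pos = 0

    # iterative shift-reduce over the token stream; no recursion limit issues
    stack: list[list] = []
    root: ParseNode | None = None
    while pos < len(tokens):
        tok = tokens[pos]
        pos += 1
        if tok == "(":
            if pos >= len(tokens) or tokens[pos] in "()":
                raise TreebankError(f"line {lineno}: missing label after '('")
            stack.append([tokens[pos]])
            pos += 1
        elif tok == ")":
            if not stack:
                raise TreebankError(f"line {lineno}: unbalanced ')'")
            label, *children = stack.pop()
            if not children:
                raise TreebankError(
                    f"line {lineno}: nonterminal {label!r} has no children"
                )
            node = ParseNode(label, children)
            if stack:
                stack[-1].append(node)
            elif root is None:
                root = node
            else:
                raise TreebankError(f"line {lineno}: multiple trees on one line")
        else:
            if not stack:
                raise TreebankError(f"line {lineno}: token {tok!r} outside tree")
            stack[-1].append(ParseNode(tok))
    if stack:
        raise TreebankError(f"line {lineno}: unbalanced '(' (missing ')')")
    if root is None:
        raise TreebankError(f"line {lineno}: no tree found")
    return root


def read_bracketed(
    source: TextIO | str, ids: Sequence[str] | None = None
) -> list[ParseTree]:
    """Read one bracketed tree per nonblank line.

    Parameters
    ----------
    source:
        Open text stream or a string of bracketed lines.
    ids:
        Optional explicit instance ids, one per tree; defaults to the
        0-based line index as a string.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    trees: list[ParseTree] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line:
            continue
        root = _parse_line(line, lineno)
        trees.append(ParseTree(str(len(trees)), root))
    if ids is not None:
        if len(ids) != len(trees):
            raise TreebankError(
                f"{len(ids)} ids supplied for {len(trees)} trees"
            )
        trees = [ParseTree(i, t.root) for i, t in zip(ids, trees)]
    return trees


def serialize_node(node: ParseNode) -> str:
    """Canonical single-line bracketed form of a (sub)tree."""
    parts: list[str] = []
    # iterative pre-order with explicit close markers
    stack: list[ParseNode | str] = [node]
    while stack:
        item = stack.pop()
        if isinstance(item, str):
            parts.append(item)
            continue
        if item.is_terminal:
            parts.append(" " + item.label)
        else:
            parts.append(("" if not parts else " ") + "(" + item.label)
            stack.append(")")
            stack.extend(reversed(item.children))
    return "".join(parts).replace(" )", ")")


def write_bracketed(trees: Iterable[ParseTree]) -> str:
    """One tree per line; read_bracketed(write_bracketed(ts)) round-trips."""
    return "".join(serialize_node(t.root) + "\n" for t in trees)


def productions_of(tree: ParseTree) -> list[Production]:
    """One production per internal node, preterminals included (POS -> word).

    Counting identity: node count = len(productions_of) + number of terminals.
    """
    return [n.production() for n in tree.root.internal_nodes()]


# ---------------------------------------------------------------------------
# label i/o

_LABEL_ALIASES = {
    "+1": +1, "1": +1, "pos": +1, "positive": +1,
    "-1": -1, "−1": -1, "neg": -1, "negative": -1,
}


def read_labels(source: TextIO | str) -> dict[str, int]:
    """Read a two-column TSV ``instance_id<TAB>label`` into {id: +1/-1}.

    Accepts ``+1/1/pos/positive`` and ``-1/neg/negative`` label spellings.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    labels: dict[str, int] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) != 2:
            raise TreebankError(f"line {lineno}: expected 2 columns, got {len(fields)}")
        iid, tok = fields[0].strip(), fields[1].strip()
        if iid in labels:
            raise TreebankError(f"line {lineno}: duplicate instance id {iid!r}")
        try:
            labels[iid] = _LABEL_ALIASES[tok.lower()]
        except KeyError:
            raise TreebankError(
                f"line {lineno}: unknown label {tok!r} (want +1/-1/pos/neg)"
            ) from None
    return labels


def write_labels(labels: Mapping[str, int]) -> str:
    return "".join(f"{iid}\t{lab:+d}\n" for iid, lab in labels.items())
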