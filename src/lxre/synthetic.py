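"""Synthetic labeled parse-tree corpora with controllable class signal.

Real relation-extraction corpora (e.g. AIMed-style protein-interaction
sentences) arrive as constituency parses with a binary relation label.  This
module emulates that setting without a parser: trees are sampled from a
small PCFG backbone shared by both classes, and each class is marked by a
**signature constituent** — a subtree adjoined under the root whose internal
productions occur in no other class.  With ``signature_prob = 1`` a single
production separates the classes perfectly; lowering it blurs the signal.

The adversary for semisupervised bootstrapping is the **distractor**: a tree
whose structure comes from a second, disjoint backbone (no production shared
with the main one) but which carries the *opposite* class's signature.  A
pair of classifiers trained on clean seeds will confidently mislabel it —
the seed-set drift failure mode — while its overall similarity to the seed
trees stays low, which is exactly the handle the similarity-constrained
admission rule uses to keep it out.

All sampling is driven by a single integer seed and is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .treebank import LabeledCorpus, ParseNode, ParseTree, read_bracketed

__all__ = [
    "GrammarSpec",
    "SyntheticCorpus",
    "Benchmark",
    "default_spec",
    "generate_corpus",
    "make_benchmark",
    "GenerationError",
]

# rules: nonterminal -> list of (children, probability); a child that is not
# itself a rule key is a terminal token.
Rules = dict[str, list[tuple[tuple[str, ...], float]]]


class GenerationError(RuntimeError):
    """Grammar cannot produce a valid bounded tree."""


@dataclass(frozen=True)
class GrammarSpec:
    backbone: "Rules"
    start: str
    signature_pos: str  # bracketed subtree adjoined under the root of class +1
    signature_neg: str
    distractor_backbone: "Rules"
    distractor_start: str
    signature_prob: float = 1.0
    distractor_prob: float = 0.0
    max_depth: int = 12
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        for p in (self.signature_prob, self.distractor_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for name, rules in (("backbone", self.backbone),
                            ("distractor_backbone", self.distractor_backbone)):
            for lhs, expansions in rules.items():
                total = sum(p for _, p in expansions)
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"{name} rule {lhs!r}: probabilities sum to {total}"
                    )

    def replace(self, **kw) -> "GrammarSpec":
        from dataclasses import replace as _replace
        return _replace(self, **kw)


def default_spec(
    signature_prob: float = 1.0, distractor_prob: float = 0.0
) -> GrammarSpec:
    """A small declarative-sentence backbone with class-unique signatures.

    Positive trees gain a ``with``-PP naming a cofactor; negative trees an
    ``alone`` adverbial.  Distractors use a question-like backbone whose
    nonterminals and vocabulary are disjoint from the declarative one.
    """
    backbone: Rules = {
        "S": [(("NP", "VP"), 1.0)],
        "NP": [(("DT", "NN"), 0.5), (("DT", "JJ", "NN"), 0.25), (("NN",), 0.25)],
        "VP": [(("VB", "NP"), 0.5), (("VB", "PP"), 0.3), (("VB",), 0.2)],
        "PP": [(("IN", "NP"), 1.0)],
        "DT": [(("the",), 0.5), (("a",), 0.5)],
        "JJ": [(("human",), 0.4), (("novel",), 0.3), (("stable",), 0.3)],
        "NN": [(("protein",), 0.25), (("kinase",), 0.25),
               (("receptor",), 0.25), (("complex",), 0.25)],
        "VB": [(("binds",), 0.25), (("inhibits",), 0.25),
               (("encodes",), 0.25), (("regulates",), 0.25)],
        "IN": [(("with",), 0.5), (("in",), 0.5)],
    }
    distractor: Rules = {
        "SBARQ": [(("WHNP", "SQ"), 1.0)],
        "WHNP": [(("WDT",), 1.0)],
        "WDT": [(("which",), 1.0)],
        "SQ": [(("MD", "VPQ"), 1.0)],
        "MD": [(("can",), 0.5), (("might",), 0.5)],
        "VPQ": [(("VBQ", "NPQ"), 0.6), (("VBQ",), 0.4)],
        "VBQ": [(("dissolve",), 0.5), (("vanish",), 0.5)],
        "NPQ": [(("NNQ",), 1.0)],
        "NNQ": [(("solvents",), 0.5), (("crystals",), 0.5)],
    }
    return GrammarSpec(
        backbone=backbone,
        start="S",
        signature_pos="(PP-CF (IN-CF with) (NP-CF (DT-CF the) (NN-CF cofactor)))",
        signature_neg="(ADVP-AL (RB-AL alone))",
        distractor_backbone=distractor,
        distractor_start="SBARQ",
        signature_prob=signature_prob,
        distractor_prob=distractor_prob,
    )


@dataclass(frozen=True)
class TreeAudit:
    """Per-tree generation record kept for test inspection."""

    true_label: int
    has_signature: bool
    is_distractor: bool


@dataclass
class SyntheticCorpus(LabeledCorpus):
    audit: dict[str, TreeAudit] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def _expand(
    rules: Rules, symbol: str, rng: np.random.Generator, depth: int, max_depth: int
) -> ParseNode:
    if symbol not in rules:
        return ParseNode(symbol)  # terminal token
    if depth > max_depth:
        raise _DepthOverflow()
    expansions = rules[symbol]
    probs = [p for _, p in expansions]
    choice = rng.choice(len(expansions), p=probs)
    children = [
        _expand(rules, child, rng, depth + 1, max_depth)
        for child in expansions[choice][0]
    ]
    return ParseNode(symbol, children)


class _DepthOverflow(Exception):
    pass


def _sample_tree(
    rules: Rules,
    start: str,
    rng: np.random.Generator,
    max_depth: int,
    max_attempts: int,
) -> ParseNode:
    for _ in range(max_attempts):
        try:
            return _expand(rules, start, rng, 0, max_depth)
        except _DepthOverflow:
            continue
    raise GenerationError(
        f"no tree of depth <= {max_depth} from {start!r} in {max_attempts} attempts"
    )


def _parse_signature(text: str) -> ParseNode:
    [tree] = read_bracketed(text)
    return tree.root


def _one_instance(
    spec: GrammarSpec, label: int, rng: np.random.Generator
) -> tuple[ParseNode, TreeAudit]:
    sig = {+1: _parse_signature(spec.signature_pos),
           -1: _parse_signature(spec.signature_neg)}
    if rng.random() < spec.distractor_prob:
        root = _sample_tree(
            spec.distractor_backbone, spec.distractor_start, rng,
            spec.max_depth, spec.max_attempts,
        )
        root = ParseNode(root.label, (*root.children, sig[-label]))
        return root, TreeAudit(label, has_signature=True, is_distractor=True)
    root = _sample_tree(
        spec.backbone, spec.start, rng, spec.max_depth, spec.max_attempts
    )
    has_sig = rng.random() < spec.signature_prob
    if has_sig:
        root = ParseNode(root.label, (*root.children, sig[label]))
    return root, TreeAudit(label, has_signature=has_sig, is_distractor=False)


def generate_corpus(
    spec: GrammarSpec,
    n_pos: int,
    n_neg: int,
    rng_seed: int,
    id_prefix: str = "t",
) -> SyntheticCorpus:
    """Sample a labeled corpus of exactly ``n_pos`` + ``n_neg`` trees.

    Class order is interleaved deterministically; ids are ``{prefix}{k}``.
    The returned corpus carries a per-tree :class:`TreeAudit`.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValueError("negative corpus sizes")
    rng = np.random.default_rng(rng_seed)
    wanted = [+1] * n_pos + [-1] * n_neg
    # deterministic interleave so prefixes of the corpus stay near-balanced
    order = np.argsort(rng.random(len(wanted)), kind="stable")
    trees: list[ParseTree] = []
    labels: dict[str, int] = {}
    audit: dict[str, TreeAudit] = {}
    for k, idx in enumerate(order):
        label = wanted[idx]
        root, rec = _one_instance(spec, label, rng)
        iid = f"{id_prefix}{k}"
        trees.append(ParseTree(iid, root))
        labels[iid] = label
        audit[iid] = rec
    return SyntheticCorpus(trees=trees, labels=labels, audit=audit)


@dataclass
class Benchmark:
    """A seed set plus an unlabeled pool with hidden ground truth.

    The labeled seed set is always clean (no distractors): it plays the role
    of the hand-labeled sentences a practitioner starts from.  Distractors,
    if any, live only in the pool.
    """

    labeled: SyntheticCorpus
    unlabeled: list[ParseTree]
    truth: dict[str, int]
    audit: dict[str, TreeAudit]

    @property
    def distractor_ids(self) -> set[str]:
        return {i for i, a in self.audit.items() if a.is_distractor}


def make_benchmark(
    spec: GrammarSpec, n_labeled: int, n_unlabeled: int, rng_seed: int
) -> Benchmark:
    """Stratified seed set + pool mirroring the seed/pool experimental layout."""
    if n_labeled < 4 or n_labeled % 2:
        raise ValueError("n_labeled must be even and >= 4 (2 per class per half)")
    clean = spec.replace(distractor_prob=0.0)
    labeled = generate_corpus(
        clean, n_labeled // 2, n_labeled // 2, rng_seed, id_prefix="seed"
    )
    pool = generate_corpus(
        spec,
        n_unlabeled - n_unlabeled // 2,
        n_unlabeled // 2,
        rng_seed + 1_000_003,
        id_prefix="u",
    )
    return Benchmark(
        labeled=labeled,
        unlabeled=list(pool.trees),
        truth=dict(pool.labels),
        audit=dict(pool.audit),
    )
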