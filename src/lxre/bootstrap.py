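"""Dual-classifier bootstrapping with similarity-constrained seed expansion.

The LXRE procedure labels a pool of unlabeled parse trees starting from a
small labeled seed set I:

1. split the current labeled set into stratified halves I1 / I2;
2. train one precomputed-kernel SVM per half (kernels A and B);
3. predict every remaining pool instance with both models;
4. candidates are the instances on whose label both models agree;
5. a candidate is admitted into the seed set only if its parse-tree
   similarity to the *initial* seeds of its predicted class is at least the
   admission threshold tau for that class — the constraint that blocks
   semantic drift, i.e. the gradual takeover of the seed set by confidently
   mislabeled instances;
6. repeat until the pool is empty; if an iteration admits nothing (or the
   iteration cap is hit), all remaining instances receive a fallback label,
   the sign of the two models' mean decision value.

``N-LXRE`` is the same loop with step 5 removed (every agreed candidate is
admitted); ``N-RE`` never expands the seed set and labels the whole pool in
a single fallback pass.  Similarity is the cosine-normalized tree kernel;
tau is frozen from the initial seed set per class (mean or min pairwise
similarity) and never recomputed, since a threshold tracking the growing
set could itself drift.

All randomness flows from ``split_seed``; a run is bit-for-bit reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Literal, Mapping, Sequence

import numpy as np

from . import classifier
from .kernel import GramMatrix, KernelConfig, gram_matrix
from .treebank import LabeledCorpus, ParseTree

__all__ = [
    "LxreConfig",
    "IterationRecord",
    "RunResult",
    "split_seed",
    "admission_threshold",
    "candidate_similarity",
    "fallback_label",
    "run",
]

Mode = Literal["LXRE", "N_LXRE", "N_RE"]

# slack for >= comparisons against tau: an exact seed copy must never be
# rejected for a last-bit rounding difference
_SIM_EPS = 1e-9


# classification default: SST, decay 0.4, cosine-normalized.  Undamped
# (decay = 1) subset-tree kernels are dominated by each tree's own large
# fragments, so the normalized Gram matrix collapses toward the identity and
# the SVM degenerates to majority voting; 0.4 is the conventional damping in
# the convolution-tree-kernel literature.
_DEFAULT_CLF_KERNEL = KernelConfig("SST", 0.4, True)


@dataclass(frozen=True)
class LxreConfig:
    mode: Mode = "LXRE"
    kernel_a: KernelConfig = _DEFAULT_CLF_KERNEL
    kernel_b: KernelConfig = _DEFAULT_CLF_KERNEL
    c_param: float = 1.0
    split_seed: int = 0
    max_iterations: int = 50
    threshold_rule: Literal["mean_pairwise", "min_pairwise"] = "mean_pairwise"
    aggregation_rule: Literal["mean", "max"] = "mean"
    balance_classes: bool = False

    def similarity_kernel(self) -> KernelConfig:
        """Normalized version of kernel A, used for tau and candidate scores."""
        return KernelConfig(self.kernel_a.variant, self.kernel_a.decay, True)


@dataclass
class IterationRecord:
    """Audit trail of one pass: who agreed, who got in, who was held back."""

    iteration: int
    pool_size: int
    agreed: list[str]
    admitted: list[str]
    rejected: list[str]  # agreed but below tau; stay in the pool
    forced: list[str]  # labeled by the fallback rule this iteration

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class RunResult:
    labels: dict[str, int]
    iteration_admitted: dict[str, int]  # 0 = forced / single-pass
    route: dict[str, str]  # agreed+similar | agreed | forced
    history: list[IterationRecord]
    thresholds: dict[int, float]

    def predictions_tsv(self) -> str:
        lines = ["instance_id\tlabel\titeration_admitted\tadmission_route"]
        for iid in self.labels:
            lines.append(
                f"{iid}\t{self.labels[iid]:+d}\t"
                f"{self.iteration_admitted[iid]}\t{self.route[iid]}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# pieces


def split_seed(
    labeled: LabeledCorpus, seed: int
) -> tuple[list[str], list[str]]:
    """Class-stratified random halves of the labeled ids.

    Each class is shuffled and dealt alternately, so the halves differ by at
    most one instance per class; both halves are trainable whenever every
    class has at least two members.
    """
    by_class: dict[int, list[str]] = {+1: [], -1: []}
    for iid in labeled.ids:
        if iid not in labeled.labels:
            raise ValueError(f"instance {iid!r} has no label")
        by_class[labeled.labels[iid]].append(iid)
    for cls, members in by_class.items():
        if len(members) < 2:
            raise ValueError(
                f"class {cls:+d} has {len(members)} labeled instance(s); "
                "need at least 2 to split"
            )
    rng = np.random.default_rng(seed)
    half1: list[str] = []
    half2: list[str] = []
    for k, cls in enumerate((+1, -1)):
        members = list(by_class[cls])
        rng.shuffle(members)
        # alternate which half takes the odd member so the overall sizes
        # also differ by at most one
        start = k % 2
        half1.extend(members[start::2])
        half2.extend(members[1 - start::2])
    return half1, half2


def _pairwise_block(sim: GramMatrix, ids: Sequence[str]) -> np.ndarray:
    return sim.submatrix(ids, ids)


def admission_threshold(
    initial_labeled: LabeledCorpus,
    sim: GramMatrix,
    threshold_rule: str = "mean_pairwise",
) -> dict[int, float]:
    """Per-class admission threshold tau from the initial seed set.

    tau_c aggregates the normalized kernel over all unordered pairs of
    initial seeds of class c (mean by default, min as the lenient-outlier
    alternative).  A class with a single seed gets tau = 0 with a warning:
    the constraint is vacuous there.
    """
    import warnings

    taus: dict[int, float] = {}
    for cls in (+1, -1):
        ids = [i for i in initial_labeled.ids if initial_labeled.labels.get(i) == cls]
        if len(ids) < 2:
            warnings.warn(
                f"class {cls:+d} has {len(ids)} seed(s); "
                "admission constraint is vacuous (tau = 0)",
                stacklevel=2,
            )
            taus[cls] = 0.0
            continue
        block = _pairwise_block(sim, ids)
        iu = np.triu_indices(len(ids), k=1)
        pair_values = block[iu]
        if threshold_rule == "mean_pairwise":
            taus[cls] = float(pair_values.mean())
        elif threshold_rule == "min_pairwise":
            taus[cls] = float(pair_values.min())
        else:
            raise ValueError(f"unknown threshold_rule {threshold_rule!r}")
    return taus


def candidate_similarity(
    candidate_id: str,
    predicted_class: int,
    initial_labeled: LabeledCorpus,
    sim: GramMatrix,
    aggregation_rule: str = "mean",
) -> float:
    """Similarity of a candidate to the initial seeds of its predicted class."""
    ids = [
        i for i in initial_labeled.ids
        if initial_labeled.labels.get(i) == predicted_class
    ]
    if not ids:
        raise ValueError(f"no initial seeds of class {predicted_class:+d}")
    row = sim.submatrix([candidate_id], ids)[0]
    if aggregation_rule == "mean":
        return float(row.mean())
    if aggregation_rule == "max":
        return float(row.max())
    raise ValueError(f"unknown aggregation_rule {aggregation_rule!r}")


def fallback_label(f_a: float, f_b: float) -> int:
    """Sign of the mean decision value; an exact tie resolves to +1."""
    return 1 if (f_a + f_b) / 2.0 >= 0.0 else -1


# ---------------------------------------------------------------------------
# the loop


def _train_half(
    gram: GramMatrix,
    half_ids: Sequence[str],
    labels: Mapping[str, int],
    kernel: KernelConfig,
    config: LxreConfig,
) -> classifier.TrainedModel:
    sub = GramMatrix(
        ids=list(half_ids),
        values=gram.submatrix(half_ids, half_ids),
        config=kernel,
    )
    return classifier.train(
        sub,
        {i: labels[i] for i in half_ids},
        c_param=config.c_param,
        balance_classes=config.balance_classes,
    )


def run(
    labeled: LabeledCorpus,
    unlabeled: Sequence[ParseTree],
    config: LxreConfig,
) -> RunResult:
    """Label every pool instance; return labels, audit history, thresholds."""
    pool_ids = [t.instance_id for t in unlabeled]
    overlap = set(labeled.ids) & set(pool_ids)
    if overlap:
        raise ValueError(f"ids present in both sets: {sorted(overlap)[:5]}")
    if not pool_ids:
        raise ValueError("unlabeled pool is empty")

    all_trees = list(labeled.trees) + list(unlabeled)

    # one Gram matrix per distinct kernel config, over all instances at once;
    # training/prediction below only index submatrices
    grams: dict[KernelConfig, GramMatrix] = {}
    for cfg in (config.kernel_a, config.kernel_b, config.similarity_kernel()):
        if cfg not in grams:
            grams[cfg] = gram_matrix(all_trees, cfg)
    gram_a = grams[config.kernel_a]
    gram_b = grams[config.kernel_b]
    sim = grams[config.similarity_kernel()]

    initial = labeled.subset(labeled.ids)  # frozen reference seed set
    taus = admission_threshold(initial, sim, config.threshold_rule)

    labels: dict[str, int] = dict(labeled.labels)
    out_labels: dict[str, int] = {}
    out_iter: dict[str, int] = {}
    out_route: dict[str, str] = {}
    history: list[IterationRecord] = []
    current_ids = list(labeled.ids)
    pool = list(pool_ids)

    single_pass = config.mode == "N_RE"
    max_iter = 1 if single_pass else config.max_iterations

    for iteration in range(1, max_iter + 1):
        train_ids = list(initial.ids) if single_pass else current_ids
        seed = np.random.default_rng((config.split_seed, iteration)).integers(2**31)
        corpus_now = LabeledCorpus(
            trees=[t for t in all_trees if t.instance_id in set(train_ids)],
            labels={i: labels[i] for i in train_ids},
        )
        i1, i2 = split_seed(corpus_now, int(seed))
        model_a = _train_half(gram_a, i1, labels, config.kernel_a, config)
        model_b = _train_half(gram_b, i2, labels, config.kernel_b, config)

        rows_a = gram_a.submatrix(pool, i1)
        rows_b = gram_b.submatrix(pool, i2)
        lab_a, f_a = classifier.predict(model_a, rows_a)
        lab_b, f_b = classifier.predict(model_b, rows_b)

        agreed: list[str] = []
        admitted: list[str] = []
        rejected: list[str] = []
        pred = {}
        for k, iid in enumerate(pool):
            pred[iid] = (int(lab_a[k]), float(f_a[k]), float(f_b[k]))
            if lab_a[k] != lab_b[k]:
                continue
            agreed.append(iid)
            if single_pass:
                continue
            if config.mode == "LXRE":
                s = candidate_similarity(
                    iid, int(lab_a[k]), initial, sim, config.aggregation_rule
                )
                if s + _SIM_EPS < taus[int(lab_a[k])]:
                    rejected.append(iid)
                    continue
            admitted.append(iid)

        stalled = not admitted
        forced: list[str] = []
        if single_pass or stalled or iteration == max_iter:
            # fallback-label whatever the loop will not place by admission
            leftover = [i for i in pool if i not in set(admitted)]
            for iid in leftover:
                _, fa, fb = pred[iid]
                out_labels[iid] = fallback_label(fa, fb)
                out_iter[iid] = 0
                out_route[iid] = "forced"
                forced.append(iid)

        route = "agreed+similar" if config.mode == "LXRE" else "agreed"
        for iid in admitted:
            lab = pred[iid][0]
            out_labels[iid] = lab
            out_iter[iid] = iteration
            out_route[iid] = route
            labels[iid] = lab
            current_ids.append(iid)

        history.append(
            IterationRecord(
                iteration=iteration,
                pool_size=len(pool),
                agreed=agreed,
                admitted=admitted,
                rejected=rejected,
                forced=forced,
            )
        )
        pool = [i for i in pool if i not in out_labels]
        if not pool:
            break

    assert not pool, "loop exited with unlabeled instances"
    # stable output order = input pool order
    ordered = {i: out_labels[i] for i in pool_ids}
    return RunResult(
        labels=ordered,
        iteration_admitted={i: out_iter[i] for i in pool_ids},
        route={i: out_route[i] for i in pool_ids},
        history=history,
        thresholds=taus,
    )
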