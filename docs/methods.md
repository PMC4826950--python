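# Methods

## Trees and corpora

Instances are constituency parse trees in the Penn-Treebank bracketed
dialect (one tree per line; literal parentheses in tokens encoded
`-LRB-`/`-RRB-`, as statistical parsers emit). Labels (+1 relation,
−1 none) live in a separate two-column TSV so the tree file remains a pure
standard format. Node labels are case-sensitive and never normalized:
both kernels compare labels by string equality, so any normalization would
silently change kernel values. Whole-sentence trees are assumed; scoping
a tree to the relation arguments (path-enclosed subtrees and similar) is
left to upstream preprocessing.

## Kernels

For internal nodes n₁, n₂ with equal productions,

    Δ(n₁, n₂) = λ                                  (both preterminal)
    Δ(n₁, n₂) = λ · Πᵢ (1 + Δ(c₁ᵢ, c₂ᵢ))           (SST)
    Δ(n₁, n₂) = λ · Πᵢ Δ(c₁ᵢ, c₂ᵢ)                 (ST)

over nonterminal child pairs (terminal children are already matched by the
production and contribute factor 1); Δ = 0 when productions differ.
K(T₁,T₂) sums Δ over all internal-node pairs. At λ = 1 this equals
Σ_f c₁(f)·c₂(f) over fragment types f, where cᵢ counts *occurrences* — a
dot product, not a min-intersection; the two differ as soon as a fragment
repeats within one tree, and the enumeration oracle and its tests use the
dot-product semantics deliberately.

Numerical and structural choices:

* **Evaluation order.** Δ is computed bottom-up over node pairs grouped by
  production and ordered by subtree height, so no recursion is involved
  and trees of height in the hundreds are handled routinely (covered by a
  test at height ≈ 300).
* **Decay λ** (default 1.0 in `KernelConfig`): 1.0 is the literal
  common-fragment count and is what the oracle equivalence tests use.
* **Normalization** (default on): cosine normalization computed from the
  unnormalized kernel; the normalized Gram diagonal is set to exactly 1.
* **Gram matrices** are computed upper-triangle-and-mirror, hence exactly
  symmetric; they export to TSV at 17 significant digits so a round-trip
  stays within 1e−9.
* **Children are ordered** and productions are never sorted — constituency
  order is meaningful.
* The brute-force `enumerate_fragments` guards at a configurable fragment
  budget (default 200) because SST fragment counts grow exponentially in
  node fan-out; it exists as an oracle, not as a production path.

## Classifier

A binary soft-margin SVM on the precomputed Gram matrix; the dual
optimisation is delegated to scikit-learn's `SVC(kernel="precomputed")`
with solver tolerance 1e−8 (tight enough that decision values are invariant
to training-order permutation within 1e−6). The model surface is the dual
form — support ids, signed coefficients αᵢyᵢ, bias — bound to its kernel
configuration and training-id order, persisted as JSON text with 17
significant digits so reloaded models predict bit-identically. C defaults
to 1.0 (conventional; the method is not sensitive to it on the synthetic
benchmarks). Optional inverse-frequency class weighting is available for
heavily skewed corpora (off by default). A decision value of exactly 0
resolves to +1.

**Classification kernel default.** The bootstrapping layer defaults to
SST, λ = 0.4, normalized. With λ = 1 a tree's kernel with itself is
dominated by its own largest fragments, so after normalization the Gram
matrix of realistic corpora collapses toward the identity (median
off-diagonal ≈ 0.03 on the synthetic corpora here) and the SVM degenerates
to majority voting on anything dissimilar from the training set. λ = 0.4
is the conventional damping in the convolution-tree-kernel literature and
restores a well-conditioned matrix (median off-diagonal ≈ 0.3). The
kernel module's own default stays λ = 1 so that kernel values are the
plain fragment counts the oracle reproduces.

## The bootstrapping loop

Design points where the procedure is genuinely underdetermined, and the
choices made:

* **Both classifiers share the run's kernel variant** by default
  (`kernel_a = kernel_b`), matching how results are reported per variant;
  an ST + SST ensemble is available by configuring the two kernels
  differently.
* **τ is frozen** from the initial seed set, per class: mean pairwise
  normalized kernel among initial seeds of the class (minimum available as
  `min_pairwise`). Recomputing τ from the growing set would let the
  threshold itself drift. Per-class thresholds matter because the two
  classes need not be equally homogeneous. A singleton class yields τ = 0
  with a warning — the constraint is vacuous there.
* **Candidate similarity** aggregates mean (default) or max normalized
  kernel against the initial seeds of the predicted class. Admission uses
  ≥ with 1e−9 slack so an exact seed copy can never be rejected by a
  last-bit rounding difference.
* **I1/I2 are re-split every iteration** (fresh stratified halves of the
  grown labeled set, dealt so halves differ by ≤1 overall and per class),
  so both classifiers see newly admitted seeds.
* **Batch admission**: every passing candidate is admitted each iteration;
  there is no top-k ranking.
* **Rejected candidates stay in the pool** — they get another chance as
  the models improve.
* **Stall fallback**: if an iteration admits nothing (or the iteration cap,
  default 50, is reached) every remaining instance is labeled with the
  sign of the two models' mean decision value (tie → +1), flagged
  `forced` in the audit trail. N-RE uses exactly this rule for its single
  pass. Termination in ≤ max_iterations passes is therefore structural.
* All randomness derives from `split_seed` (one child seed per iteration),
  so a run is reproducible bit for bit.

## Metrics

Precision tp/(tp+fp), Recall tp/(tp+fn), Accuracy (tp+tn)/total, and
F = 2PR/(P+R), all as percentages; zero denominators yield NaN with a
warning, never a silent 0. Display rounding is half-up to two decimals,
matching the published tables; internal values are unrounded. The
positive class is "relation present". Relative improvement is
100·(a−b)/b; the comparison grid pits a reference algorithm's accuracy
against the best and worst competitor per condition. The published
PropBank/AIMed tables are embedded verbatim in `reference_results.py` as
fixed inputs for these arithmetic checks.

## Synthetic data

The generator emulates the seed-set + pool layout of a parsed binary
relation corpus. Both classes share a small declarative-sentence PCFG
backbone (S → NP VP with noun-phrase, verb-phrase and prepositional
expansions over a small vocabulary); a class is marked by a **signature
constituent** adjoined under the root (positive: a cofactor-PP; negative:
an "alone" adverbial) whose node labels occur nowhere else, so with
`signature_prob = 1` a single production separates the classes.
Sampling is top-down with rejection of trees exceeding the depth bound
(default 12; a generation error after 1000 attempts). Distractors are
sampled from a second backbone with disjoint nonterminals and vocabulary
and carry the *opposite* class's signature: both classifiers therefore
agree on the wrong label, while the tree's overall similarity to any seed
stays far below τ. Benchmarks place distractors only in the pool — the
seed set plays the role of trusted hand labels. Defaults used by the
benchmark suites: 20 seeds + 100 pool instances, `signature_prob = 1`,
and `distractor_prob = 0` (separable) or 0.15 (adversarial), with 10
replicate seeds.

What the generator does **not** emulate: natural-language lexical
diversity, parser error patterns, class imbalance of real interaction
corpora (positives ≈ 24% in AIMed-like data), or graded signature overlap
between classes. Passing benchmarks therefore demonstrate the mechanics
of the algorithms — kernel correctness, admission behavior, drift
blocking — not expected accuracy on real corpora.

## Limitations

* The admission threshold's mean-pairwise default is strict: roughly half
  of in-distribution candidates can fall below it in early iterations,
  which shifts work to later iterations or the fallback. `min_pairwise`
  is the lenient alternative.
* Kernel evaluation is exact and O(|N₁|·|N₂|) per pair; corpora of a few
  hundred trees are comfortable, tens of thousands are not.
* Only binary labels, ST/SST variants, and single-kernel-per-classifier
  runs are supported; partial-tree kernels and kernel/feature-vector
  combinations are out of scope.
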