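# lxre — semisupervised relation extraction with convolution tree kernels

`lxre` implements the **LXRE** family of algorithms for sentence-level
relation extraction (e.g. deciding whether a biomedical sentence asserts a
protein–protein interaction) when only a handful of labeled sentences are
available next to a large unlabeled pool. Sentences are represented by
their constituency parse trees; parsing itself is out of scope — the
package consumes Penn-Treebank bracketed trees, one per line, as emitted by
standard statistical parsers.

## The method

**Convolution tree kernels.** The similarity of two parse trees T₁, T₂ is
the number of tree fragments they share,

    K(T₁, T₂) = Σ_{n₁∈N₁} Σ_{n₂∈N₂} Δ(n₁, n₂),

where Nᵢ are the internal nodes and Δ(n₁, n₂) counts common fragments
rooted at the pair via a production-matching recursion. Two fragment
languages are provided: **ST** (subtree — a fragment is the complete
subtree below a node) and **SST** (subset tree — each included node either
expands its full production or stops, so fragments need not reach the
leaves; a strict generalization of ST). A decay factor λ ∈ (0, 1] damps
large fragments and cosine normalization K̂ = K(a,b)/√(K(a,a)K(b,b)) makes
trees of different sizes comparable. A brute-force fragment-enumeration
oracle is included and the dynamic program is tested against it.

**LXRE bootstrapping.** Starting from a labeled seed set I and a pool II:
split I into stratified halves I1/I2; train one precomputed-kernel SVM per
half; predict the pool with both; instances on which both models **agree**
become candidates; a candidate is **admitted** into the seed set only if
its normalized kernel similarity to the *initial* seeds of its predicted
class reaches the per-class threshold τ (mean pairwise similarity among the
initial seeds); repeat until the pool is empty, with a deterministic
fallback (sign of the two models' mean decision value) for whatever the
loop cannot place. The similarity constraint is what blocks *semantic
drift* — the gradual takeover of the seed set by confidently mislabeled
instances. Two ablations are built in: **N-LXRE** (no similarity
constraint) and **N-RE** (no seed expansion; single supervised pass).

Because public relation corpora and their parses are not redistributable,
the package ships a PCFG generator that emulates the experimental layout:
labeled parse trees whose classes differ by signature constituents, plus
off-distribution *distractor* trees carrying the opposite class's signature
— the exact adversary the admission constraint exists to reject.

## A worked example

```sh
python examples/bootstrap_lxre.py
```

```
20 seeds, 100 pool instances, 18 distractors

LXRE    accuracy=82.0%  admitted= 39  distractors admitted= 0  iterations=2
N_LXRE  accuracy=82.0%  admitted=100  distractors admitted=18  iterations=1
N_RE    accuracy=82.0%  admitted=  0  distractors admitted= 0  iterations=1
```

All three modes label every pool instance, and on this benchmark they agree
on the final labels. The mechanism of interest is the third column: the
18 distractors fool *both* agreeing classifiers, so the unconstrained
N-LXRE absorbs all of them into its training seed set, while LXRE's
similarity threshold admits none — on harder corpora that contamination is
what degrades later iterations. `examples/kernel_basics.py`,
`examples/train_and_classify.py` and `examples/published_tables.py` walk
the kernel arithmetic, the SVM layer, and the published evaluation tables.

The same pipeline is scriptable from a shell:

```sh
lxre synth --n-pos 10 --n-neg 10 --seed 1 --out-prefix seed
lxre synth --n-pos 50 --n-neg 50 --seed 2 --out-prefix pool
lxre run --labeled-trees seed.trees --labels seed.labels.tsv \
         --unlabeled-trees pool.trees --mode lxre --seed 0 --out-dir run1
lxre eval --pred run1/predictions.tsv --truth pool.labels.tsv
```

Every run directory contains the predictions TSV (instance, label,
admission iteration and route), a line-delimited audit log of each
iteration's agreed/admitted/rejected/forced sets, and the resolved
configuration; identical configuration and seed reproduce the outputs
byte for byte.

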