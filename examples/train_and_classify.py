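"""Train a precomputed-kernel SVM on a synthetic relation corpus.

Generates a perfectly separable corpus (every positive tree carries the
positive signature constituent), builds the normalized SST Gram matrix,
fits the SVM, and scores held-out trees.
"""

from lxre import KernelConfig, evaluate, generate_corpus, gram_matrix
from lxre.classifier import predict, train
from lxre.kernel import kernel_row
from lxre.synthetic import default_spec

spec = default_spec(signature_prob=1.0, distractor_prob=0.0)
train_corpus = generate_corpus(spec, 15, 15, rng_seed=0)
test_corpus = generate_corpus(spec, 25, 25, rng_seed=1, id_prefix="test")

cfg = KernelConfig("SST", decay=0.4, normalize=True)
gram = gram_matrix(train_corpus.trees, cfg)
model = train(gram, train_corpus.labels, c_param=1.0)
print(f"trained on {len(train_corpus)} trees; "
      f"{len(model.support_ids)} support vectors")

predicted = {}
for tree in test_corpus.trees:
    row = kernel_row(tree, train_corpus.trees, cfg)
    label, _ = predict(model, row)
    predicted[tree.instance_id] = int(label[0])

report = evaluate(predicted, test_corpus.labels).rounded()
print(f"held-out: P={report.precision}% R={report.recall}% "
      f"F={report.f_measure}% Acc={report.accuracy}%")
print()
print("With an unambiguous class signature in every tree the kernel SVM "
      "separates the classes exactly, so all four indexes reach 100%.")
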