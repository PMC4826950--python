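"""The constrained seed-expansion loop and its ablations."""

import numpy as np
import pytest

from lxre import bootstrap
from lxre.bootstrap import (
    LxreConfig,
    admission_threshold,
    candidate_similarity,
    fallback_label,
    split_seed,
)
from lxre.kernel import KernelConfig, gram_matrix, tree_kernel
from lxre.synthetic import default_spec, generate_corpus, make_benchmark
from lxre.treebank import LabeledCorpus, ParseTree

SIM = KernelConfig("SST", 0.4, True)


def _corpus(n_pos=5, n_neg=5, seed=0):
    return generate_corpus(default_spec(1.0, 0.0), n_pos, n_neg, seed)


class TestSplitSeed:
    def test_partition_contract(self):
        corpus = _corpus(5, 5)
        i1, i2 = split_seed(corpus, 0)
        assert not set(i1) & set(i2)
        assert sorted(i1 + i2) == sorted(corpus.ids)
        assert abs(len(i1) - len(i2)) <= 1

    def test_stratified_within_one_per_class(self):
        corpus = _corpus(6, 4)
        i1, i2 = split_seed(corpus, 3)
        for cls in (+1, -1):
            n1 = sum(corpus.labels[i] == cls for i in i1)
            n2 = sum(corpus.labels[i] == cls for i in i2)
            assert abs(n1 - n2) <= 1

    def test_deterministic_given_seed(self):
        corpus = _corpus()
        assert split_seed(corpus, 9) == split_seed(corpus, 9)

    def test_two_two_splits_one_one(self):
        corpus = _corpus(2, 2)
        i1, i2 = split_seed(corpus, 0)
        for half in (i1, i2):
            assert sorted(corpus.labels[i] for i in half) == [-1, 1]

    def test_small_class_rejected(self):
        corpus = _corpus(1, 4)
        with pytest.raises(ValueError, match=r"\+1"):
            split_seed(corpus, 0)


class TestAdmissionThreshold:
    def test_identical_seeds_give_tau_one(self):
        base = _corpus(2, 2, seed=1)
        pos = [t for t in base.trees if base.labels[t.instance_id] == 1][0]
        negs = [t for t in base.trees if base.labels[t.instance_id] == -1]
        trees = [
            ParseTree("p1", pos.root), ParseTree("p2", pos.root),
            *[ParseTree(f"n{i}", t.root) for i, t in enumerate(negs)],
        ]
        corpus = LabeledCorpus(trees=trees, labels={"p1": 1, "p2": 1, "n0": -1, "n1": -1})
        sim = gram_matrix(trees, SIM)
        taus = admission_threshold(corpus, sim)
        assert taus[+1] == pytest.approx(1.0)

    def test_mean_rule_matches_direct_recomputation(self):
        corpus = _corpus(3, 3, seed=4)
        sim = gram_matrix(corpus.trees, SIM)
        taus = admission_threshold(corpus, sim, "mean_pairwise")
        for cls in (+1, -1):
            trees = [t for t in corpus.trees if corpus.labels[t.instance_id] == cls]
            pairs = [
                tree_kernel(trees[i], trees[j], SIM)
                for i in range(3) for j in range(i + 1, 3)
            ]
            assert taus[cls] == pytest.approx(np.mean(pairs))

    def test_min_rule_not_above_mean_rule(self):
        corpus = _corpus(4, 4, seed=5)
        sim = gram_matrix(corpus.trees, SIM)
        lo = admission_threshold(corpus, sim, "min_pairwise")
        hi = admission_threshold(corpus, sim, "mean_pairwise")
        assert lo[+1] <= hi[+1] and lo[-1] <= hi[-1]

    def test_singleton_class_vacuous_with_warning(self):
        base = _corpus(3, 3, seed=1)
        ids = [i for i in base.ids if base.labels[i] == -1][:1]
        keep = [i for i in base.ids if base.labels[i] == 1] + ids
        corpus = base.subset(keep)
        sim = gram_matrix(corpus.trees, SIM)
        with pytest.warns(UserWarning, match="vacuous"):
            taus = admission_threshold(corpus, sim)
        assert taus[-1] == 0.0


class TestCandidateSimilarity:
    def test_exact_seed_copy_scores_one_with_max(self):
        corpus = _corpus(2, 2, seed=6)
        pos_id = [i for i in corpus.ids if corpus.labels[i] == 1][0]
        cand = ParseTree("cand", corpus.tree(pos_id).root)
        trees = corpus.trees + [cand]
        sim = gram_matrix(trees, SIM)
        s = candidate_similarity("cand", +1, corpus, sim, "max")
        assert s == pytest.approx(1.0)

    def test_mean_matches_direct_recomputation(self):
        corpus = _corpus(3, 3, seed=7)
        cand_corpus = _corpus(1, 0, seed=99)
        cand = ParseTree("cand", cand_corpus.trees[0].root)
        trees = corpus.trees + [cand]
        sim = gram_matrix(trees, SIM)
        s = candidate_similarity("cand", +1, corpus, sim, "mean")
        seeds = [t for t in corpus.trees if corpus.labels[t.instance_id] == 1]
        direct = np.mean([tree_kernel(cand, t, SIM) for t in seeds])
        assert s == pytest.approx(direct)

    def test_missing_class_rejected(self):
        corpus = _corpus(0, 3, seed=8)
        sim = gram_matrix(corpus.trees, SIM)
        with pytest.raises(ValueError, match="no initial seeds"):
            candidate_similarity(corpus.ids[0], +1, corpus, sim)


class TestFallbackLabel:
    @pytest.mark.parametrize(
        "fa, fb, expected", [(0.5, 0.3, 1), (-0.5, 0.1, -1), (0.2, -0.2, 1)]
    )
    def test_sign_of_mean_with_positive_ties(self, fa, fb, expected):
        assert fallback_label(fa, fb) == expected


class TestRun:
    def test_pool_of_seed_copies_is_a_fixed_point(self):
        corpus = _corpus(6, 6, seed=10)
        pool = [ParseTree(f"copy_{t.instance_id}", t.root) for t in corpus.trees]
        res = bootstrap.run(corpus, pool, LxreConfig(mode="LXRE", split_seed=0))
        for t in corpus.trees:
            cid = f"copy_{t.instance_id}"
            assert res.labels[cid] == corpus.labels[t.instance_id]
            assert res.iteration_admitted[cid] == 1
            assert res.route[cid] == "agreed+similar"

    def test_terminates_and_labels_everything(self):
        bench = make_benchmark(default_spec(0.8, 0.1), 12, 40, 2)
        cfg = LxreConfig(mode="LXRE", split_seed=2, max_iterations=5)
        res = bootstrap.run(bench.labeled, bench.unlabeled, cfg)
        assert set(res.labels) == set(bench.truth)
        assert len(res.history) <= 5

    def test_history_replays_admission_soundness(self):
        bench = make_benchmark(default_spec(1.0, 0.15), 16, 60, 3)
        cfg = LxreConfig(mode="LXRE", split_seed=3)
        res = bootstrap.run(bench.labeled, bench.unlabeled, cfg)
        sim = gram_matrix(
            list(bench.labeled.trees) + list(bench.unlabeled),
            cfg.similarity_kernel(),
        )
        for rec in res.history:
            assert set(rec.admitted) <= set(rec.agreed)
            for iid in rec.admitted:
                s = candidate_similarity(
                    iid, res.labels[iid], bench.labeled, sim, cfg.aggregation_rule
                )
                assert s + 1e-9 >= res.thresholds[res.labels[iid]]

    def test_seed_set_only_grows_and_never_relabels(self):
        bench = make_benchmark(default_spec(0.9, 0.0), 12, 40, 4)
        res = bootstrap.run(
            bench.labeled, bench.unlabeled, LxreConfig(mode="LXRE", split_seed=4)
        )
        seen: dict[str, int] = {}
        for rec in res.history:
            for iid in rec.admitted:
                assert iid not in seen
                seen[iid] = res.labels[iid]

    def test_n_re_is_single_pass_all_forced(self):
        bench = make_benchmark(default_spec(1.0, 0.0), 12, 30, 5)
        res = bootstrap.run(
            bench.labeled, bench.unlabeled, LxreConfig(mode="N_RE", split_seed=5)
        )
        assert len(res.history) == 1
        assert all(r == "forced" for r in res.route.values())
        assert all(v == 0 for v in res.iteration_admitted.values())

    def test_n_lxre_admits_distractors_lxre_blocks_them(self):
        bench = make_benchmark(default_spec(1.0, 0.15), 16, 60, 6)
        counts = {}
        for mode in ("LXRE", "N_LXRE"):
            res = bootstrap.run(
                bench.labeled, bench.unlabeled, LxreConfig(mode=mode, split_seed=6)
            )
            counts[mode] = sum(
                1 for i in bench.distractor_ids if res.route[i] != "forced"
            )
        assert counts["LXRE"] < counts["N_LXRE"]

    def test_identical_config_reproduces_bit_identical_output(self):
        bench = make_benchmark(default_spec(1.0, 0.1), 12, 40, 7)
        cfg = LxreConfig(mode="LXRE", split_seed=7)
        r1 = bootstrap.run(bench.labeled, bench.unlabeled, cfg)
        r2 = bootstrap.run(bench.labeled, bench.unlabeled, cfg)
        assert r1.predictions_tsv() == r2.predictions_tsv()

    def test_overlapping_ids_rejected(self):
        corpus = _corpus(3, 3, seed=12)
        with pytest.raises(ValueError, match="both sets"):
            bootstrap.run(corpus, list(corpus.trees), LxreConfig())
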