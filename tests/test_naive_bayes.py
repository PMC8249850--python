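from collections import Counter
from fractions import Fraction

import numpy as np
import pytest

from ampliclass.class_weights import ClassWeights, uniform_weights
from ampliclass.kmer_features import kmer_counts
from ampliclass.naive_bayes import WeightedNaiveBayes, fit_nb
from ampliclass.refdb_io import ReferenceDB, RefRecord

from conftest import full_lineage


def exact_nb_posterior(class_bags, priors, query, alpha):
    """Rational-arithmetic multinomial Bayes oracle (shared OOV column)."""
    vocab = sorted({w for bag in class_bags.values() for w in bag})
    V = len(vocab)
    alpha = Fraction(alpha)
    scores = {}
    for c, bag in class_bags.items():
        total = sum(bag.values())
        score = Fraction(priors[c])
        for w, n in query.items():
            n_cw = bag.get(w, 0) if w in vocab else 0
            p = (n_cw + alpha) / (total + alpha * (V + 1))
            score *= p**n
        scores[c] = score
    z = sum(scores.values())
    return {c: s / z for c, s in scores.items()}


def _db_from_bags(seqs):
    return ReferenceDB(
        {f"r{i}": RefRecord(seq, lin) for i, (seq, lin) in enumerate(seqs)}
    )


class TestAgainstExactOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_instances_match_to_1e9(self, seed):
        """Posterior equals a Fraction-arithmetic Bayes computation."""
        rng = np.random.default_rng(seed)
        k = 3
        n_classes = int(rng.integers(2, 5))
        classes = [full_lineage("G", f"s{i}") for i in range(n_classes)]
        alphabet = "ACGT"
        seqs = []
        for c in classes:
            L = int(rng.integers(8, 20))
            seqs.append(("".join(rng.choice(list(alphabet), L)), c))
        db = _db_from_bags(seqs)
        pr = rng.dirichlet(np.ones(n_classes))
        weights = ClassWeights(dict(zip(classes, pr)))
        model = WeightedNaiveBayes(alpha=0.001, k=k).fit(db, weights)

        query_seq = "".join(rng.choice(list(alphabet), 12))
        query = kmer_counts(query_seq, k)
        got = model.bag_class_probabilities(query)

        class_bags = {c: kmer_counts(s, k) for s, c in seqs}
        priors = {c: p for c, p in zip(classes, pr)}
        expected = exact_nb_posterior(class_bags, priors, query, 0.001)
        for c in classes:
            assert got[c] == pytest.approx(float(expected[c]), abs=1e-9)

    def test_identical_training_posterior_equals_prior(self):
        a, b = full_lineage("G", "A"), full_lineage("G", "B")
        db = _db_from_bags([("ACGTACGTAC", a), ("ACGTACGTAC", b)])
        w = ClassWeights({a: 0.9, b: 0.1})
        model = WeightedNaiveBayes(k=3).fit(db, w)
        post = model.class_probabilities("ACGTAC")
        assert post[a] == pytest.approx(0.9, abs=1e-9)
        assert post[b] == pytest.approx(0.1, abs=1e-9)


class TestBehaviour:
    def test_single_class_posterior_is_one(self):
        a = full_lineage("G", "A")
        db = _db_from_bags([("ACGTACGT", a)])
        model = fit_nb(db, uniform_weights(db), k=3)
        assert model.class_probabilities("GGGG")[a] == pytest.approx(1.0)

    def test_disjoint_kmers_pick_matching_class(self):
        a, b = full_lineage("G", "A"), full_lineage("G", "B")
        db = _db_from_bags([("AAAAAAAAAA", a), ("CCCCCCCCCC", b)])
        model = fit_nb(db, uniform_weights(db), k=3)
        post = model.class_probabilities("AAAAAA")
        assert post[a] > 0.99

    def test_empty_bag_returns_prior(self):
        a, b = full_lineage("G", "A"), full_lineage("G", "B")
        db = _db_from_bags([("AAAAAAAAAA", a), ("CCCCCCCCCC", b)])
        w = ClassWeights({a: 0.8, b: 0.2})
        model = WeightedNaiveBayes(k=3).fit(db, w)
        post = model.bag_class_probabilities(Counter())
        assert post[a] == pytest.approx(0.8, abs=1e-12)

    def test_doubling_counts_sharpens_posterior(self):
        a, b = full_lineage("G", "A"), full_lineage("G", "B")
        db = _db_from_bags([("AAAAAACCCC", a), ("CCCCCCAAAA", b)])
        model = fit_nb(db, uniform_weights(db), k=3)
        bag = kmer_counts("AAAAAA", 3)
        p1 = model.bag_class_probabilities(bag)
        p2 = model.bag_class_probabilities(Counter({w: 2 * n for w, n in bag.items()}))
        assert p2[a] > p1[a] > 0.5

    def test_class_relabeling_symmetry(self):
        """With uniform priors and mirrored training data the posterior is
        exchangeable under swapping the class labels."""
        a, b = full_lineage("G", "A"), full_lineage("G", "B")
        db = _db_from_bags([("AAAACCCC", a), ("CCCCAAAA", b)])
        model = fit_nb(db, uniform_weights(db), k=3)
        post_a = model.class_probabilities("AAAA")
        post_b = model.class_probabilities("CCCC")
        assert post_a[a] == pytest.approx(post_b[b], abs=1e-9)

    def test_feature_log_prob_rows_normalize(self, toy_refdb):
        model = fit_nb(toy_refdb, uniform_weights(toy_refdb), k=4)
        rows = np.exp(model.feature_log_prob_).sum(axis=1)
        assert rows == pytest.approx(np.ones(len(rows)), abs=1e-9)

    def test_zero_kmer_class_is_named_error(self):
        a, b = full_lineage("G", "A"), full_lineage("G", "B")
        db = _db_from_bags([("ACGTACGTACGT", a), ("NNNNNNNNNN", b)])
        with pytest.raises(ValueError, match="B"):
            fit_nb(db, uniform_weights(db), k=7)

    def test_alpha_must_be_positive(self):
        with pytest.raises(ValueError):
            WeightedNaiveBayes(alpha=0.0)
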