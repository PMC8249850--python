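"""Multinomial naive Bayes over k-mer bags with ecological class priors.

The model is the classical multinomial NB: per class c and k-mer w,

    P(w | c) = (n_cw + alpha) / (n_c + alpha * (V + 1))

where n_cw pools the k-mer counts of every training sequence of class c,
n_c is the class's total k-mer count, and V is the training vocabulary
size.  The ``+1`` is a shared out-of-vocabulary column: a query k-mer never
seen at training contributes the alpha-smoothed floor probability instead
of zeroing the posterior.  The class prior is the taxonomic class weight,
so skewed ecological expectations tilt the posterior exactly as Bayes'
rule dictates.

Posteriors are computed in log space with max-subtraction; an empty query
bag therefore returns the prior unchanged.
"""
from __future__ import annotations

from collections import Counter

import numpy as np

from .class_weights import ClassWeights
from .kmer_features import DEFAULT_K, kmer_counts
from .rank_confidence import RankConfidenceClassifierMixin
from .refdb_io import Lineage, ReferenceDB

#: default Laplace/Lidstone pseudo-count
DEFAULT_ALPHA = 0.001


class WeightedNaiveBayes(RankConfidenceClassifierMixin):
    """Multinomial NB whose class priors are taxonomic class weights."""

    def __init__(self, alpha: float = DEFAULT_ALPHA, k: int = DEFAULT_K) -> None:
        if alpha <= 0:
            raise ValueError("alpha must be positive")
        self.alpha = float(alpha)
        self.k = int(k)
        self.classes_: list[Lineage] = []
        self.vocabulary_: dict[str, int] = {}
        self.feature_log_prob_: np.ndarray | None = None  # (C, V+1); last col = OOV
        self.log_prior_: np.ndarray | None = None

    def fit(self, refdb: ReferenceDB, weights: ClassWeights) -> "WeightedNaiveBayes":
        weights.check_bound(refdb)
        self.classes_ = refdb.species_set()
        class_index = {c: i for i, c in enumerate(self.classes_)}

        pooled: list[Counter] = [Counter() for _ in self.classes_]
        for rec in refdb.records.values():
            pooled[class_index[rec.lineage]] += kmer_counts(rec.sequence, self.k)
        for c, bag in zip(self.classes_, pooled):
            if not bag:
                raise ValueError(f"class {c} has no usable k-mers at k={self.k}")

        vocab = sorted({w for bag in pooled for w in bag})
        self.vocabulary_ = {w: j for j, w in enumerate(vocab)}
        V = len(vocab)

        counts = np.zeros((len(self.classes_), V + 1))
        for i, bag in enumerate(pooled):
            for w, n in bag.items():
                counts[i, self.vocabulary_[w]] = n
        totals = counts.sum(axis=1, keepdims=True)
        self.feature_log_prob_ = np.log(counts + self.alpha) - np.log(
            totals + self.alpha * (V + 1)
        )
        self.log_prior_ = np.log(
            np.array([weights[c] for c in self.classes_], dtype=float)
        )
        return self

    def _check_fitted(self) -> None:
        if self.feature_log_prob_ is None:
            raise RuntimeError("model is not fitted")

    def bag_class_probabilities(self, bag: Counter) -> dict[Lineage, float]:
        """Posterior over classes for one k-mer bag (prior if the bag is empty)."""
        self._check_fitted()
        scores = self.log_prior_.copy()
        oov_col = self.feature_log_prob_.shape[1] - 1
        for w, n in bag.items():
            j = self.vocabulary_.get(w, oov_col)
            scores = scores + n * self.feature_log_prob_[:, j]
        scores -= scores.max()
        post = np.exp(scores)
        post /= post.sum()
        return dict(zip(self.classes_, post))

    def class_probabilities(self, sequence: str) -> dict[Lineage, float]:
        return self.bag_class_probabilities(kmer_counts(sequence, self.k))


def fit_nb(
    refdb: ReferenceDB,
    weights: ClassWeights,
    alpha: float = DEFAULT_ALPHA,
    k: int = DEFAULT_K,
) -> WeightedNaiveBayes:
    """Convenience constructor mirroring the other classifier factories."""
    return WeightedNaiveBayes(alpha=alpha, k=k).fit(refdb, weights)
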