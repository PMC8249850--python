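"""Random-forest classification over k-mer bags with class-weight injection.

Tree induction is delegated to scikit-learn's ensemble implementation; this
module fixes the hyperparameter semantics of the benchmark grid
(n_estimators, max_depth, max_features) and the probability contract:
per-read class probabilities are the mean of per-tree leaf distributions,
handed to the shared rank-confidence assignment.

Random forests have no prior slot, so ecological class weights enter as
per-instance training weights, weight(class) / n_train(class): each class's
total training mass equals its prior probability, reproducing the prior's
effect on the training loss.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .class_weights import ClassWeights
from .kmer_features import DEFAULT_K, bags_to_matrix, build_vocabulary, kmer_counts
from .rank_confidence import RankConfidenceClassifierMixin
from .refdb_io import Lineage, ReferenceDB

#: the benchmark's hyperparameter grid
FOREST_GRID = {
    "n_estimators": (100, 1000),
    "max_depth": (16, 64, None),
    "max_features": ("sqrt", None),
}


@dataclass
class ForestConfig:
    n_estimators: int = 100
    max_depth: int | None = None
    max_features: str | None = "sqrt"
    seed: int = 0


class KmerForestClassifier(RankConfidenceClassifierMixin):
    """Ensemble of CART-style trees over bag-of-7-mers features."""

    def __init__(self, config: ForestConfig | None = None, k: int = DEFAULT_K) -> None:
        self.config = config or ForestConfig()
        self.k = int(k)
        self.classes_: list[Lineage] = []
        self.vocabulary_: dict[str, int] = {}
        self._forest: RandomForestClassifier | None = None

    def fit(self, refdb: ReferenceDB, weights: ClassWeights) -> "KmerForestClassifier":
        weights.check_bound(refdb)
        self.classes_ = refdb.species_set()
        if len(self.classes_) < 2:
            raise ValueError("forest training requires at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}

        ids = refdb.ids()
        bags = [kmer_counts(refdb.records[i].sequence, self.k) for i in ids]
        self.vocabulary_ = build_vocabulary(bags)
        X = bags_to_matrix(bags, self.vocabulary_)
        y = np.array([class_index[refdb.records[i].lineage] for i in ids])

        n_per_class = np.bincount(y, minlength=len(self.classes_))
        w = np.array([weights[c] for c in self.classes_])
        sample_weight = (w / n_per_class)[y]

        cfg = self.config
        self._forest = RandomForestClassifier(
            n_estimators=cfg.n_estimators,
            max_depth=cfg.max_depth,
            max_features=cfg.max_features,
            random_state=cfg.seed,
            n_jobs=1,
        )
        self._forest.fit(X, y, sample_weight=sample_weight)
        return self

    def class_probabilities(self, sequence: str) -> dict[Lineage, float]:
        if self._forest is None:
            raise RuntimeError("model is not fitted")
        X = bags_to_matrix([kmer_counts(sequence, self.k)], self.vocabulary_)
        proba = np.zeros(len(self.classes_))
        proba[self._forest.classes_] = self._forest.predict_proba(X)[0]
        proba /= proba.sum()
        return dict(zip(self.classes_, proba))


def fit_forest(
    refdb: ReferenceDB,
    weights: ClassWeights,
    config: ForestConfig | None = None,
    k: int = DEFAULT_K,
) -> KmerForestClassifier:
    return KmerForestClassifier(config=config, k=k).fit(refdb, weights)
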