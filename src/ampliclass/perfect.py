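"""The exact-match "perfect" classifier: an accuracy ceiling for a reference.

For every reference sequence, the index records the list of species-level
classes carrying exactly that sequence, with weights taken from the
taxonomic class-weight table (or equal weights in uniform mode) and
renormalized per sequence.  Classification is an exact string lookup
followed by the shared confidence-thresholded rank-truncation procedure:
the classifier is evaluated strictly in-sample and can only err when two or
more species share an identical sequence, so its score is the upper bound
of achievable accuracy for that reference, amplicon length, and weight
distribution.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .class_weights import ClassWeights
from .rank_confidence import RankConfidenceClassifierMixin
from .refdb_io import Assignment, Lineage, ReferenceDB


class OutOfSampleError(KeyError):
    """A query sequence is absent from the exact index.

    The perfect classifier is an in-sample construct; silently returning
    Unassigned would corrupt the upper bound it measures.
    """


@dataclass
class ExactIndex:
    """sequence -> [(class lineage, per-sequence normalized weight), ...]"""

    entries: dict[str, list[tuple[Lineage, float]]]
    mode: str

    def __len__(self) -> int:
        return len(self.entries)

    def ambiguity_report(self) -> dict[str, int]:
        """Number of distinct classes sharing each indexed sequence."""
        return {seq: len(taxa) for seq, taxa in self.entries.items()}

    def n_shared(self) -> int:
        return sum(1 for taxa in self.entries.values() if len(taxa) > 1)


def build_exact_index(
    refdb: ReferenceDB,
    weights: ClassWeights | None = None,
    trim_length: int | None = None,
) -> ExactIndex:
    """Pool identical (case-folded, optionally trimmed) sequences and attach
    per-sequence renormalized class weights.

    ``weights=None`` selects uniform mode: every class matching a sequence
    receives equal weight.
    """
    by_seq: dict[str, set[Lineage]] = defaultdict(set)
    for rec in refdb.records.values():
        seq = rec.sequence.upper()
        if trim_length is not None:
            if len(seq) < trim_length:
                continue
            seq = seq[:trim_length]
        by_seq[seq].add(rec.lineage)
    if not by_seq:
        raise ValueError("no reference sequences reach the trim length")

    entries: dict[str, list[tuple[Lineage, float]]] = {}
    for seq, taxa in by_seq.items():
        taxa_sorted = sorted(taxa)
        if weights is None:
            w = [1.0] * len(taxa_sorted)
        else:
            w = [weights[t] for t in taxa_sorted]
        total = sum(w)
        entries[seq] = [(t, wi / total) for t, wi in zip(taxa_sorted, w)]
    return ExactIndex(entries, mode="uniform" if weights is None else weights.mode)


class PerfectClassifier(RankConfidenceClassifierMixin):
    """Exact-lookup classifier over an :class:`ExactIndex`."""

    def __init__(
        self, weights: ClassWeights | None = None, trim_length: int | None = None
    ) -> None:
        self.weights = weights
        self.trim_length = trim_length
        self.index: ExactIndex | None = None

    def fit(self, refdb: ReferenceDB, weights: ClassWeights | None = None) -> "PerfectClassifier":
        if weights is not None:
            self.weights = weights
        self.index = build_exact_index(refdb, self.weights, self.trim_length)
        return self

    def class_probabilities(self, sequence: str) -> dict[Lineage, float]:
        if self.index is None:
            raise RuntimeError("index is not built")
        seq = sequence.upper()
        if self.trim_length is not None:
            seq = seq[:self.trim_length]
        taxa = self.index.entries.get(seq)
        if taxa is None:
            raise OutOfSampleError(
                "query sequence is not in the reference index; the perfect "
                "classifier is in-sample by construction"
            )
        return dict(taxa)


def perfect_classify(
    index: ExactIndex, sequence: str, confidence: float = 0.7, seed: int = 0
) -> Assignment:
    """Classify one read against a pre-built exact index."""
    from .rank_confidence import assign_with_confidence

    taxa = index.entries.get(sequence.upper())
    if taxa is None:
        raise OutOfSampleError(
            "query sequence is not in the reference index; the perfect "
            "classifier is in-sample by construction"
        )
    return assign_with_confidence(dict(taxa), confidence, seed)
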