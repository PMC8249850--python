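"""Confidence-thresholded, rank-truncating assignment shared by all classifiers.

Given a read's probability vector over species-level classes, the procedure
tests the maximum probability against a confidence threshold at the species
rank; on failure it aggregates probabilities one rank up (summing over
classes that share the genus-level prefix, then family, and so on toward
kingdom) and repeats.  If no rank ever exceeds the threshold the read is
left Unassigned.  Classes whose reference lineage is itself truncated
participate at their deepest labeled rank.

The comparison is a strict ``>``; ties among equal-maximum candidates are
broken uniformly at random with the caller's seed.
"""
from __future__ import annotations

from collections import defaultdict
from collections.abc import Mapping, Sequence

import numpy as np

from .refdb_io import Assignment, Lineage, ReadSet

_TIE_TOL = 1e-12
_SUM_TOL = 1e-6


def aggregate_at_depth(
    probs: Mapping[Lineage, float], depth: int
) -> dict[Lineage, float]:
    """Sum class probabilities over lineages truncated to ``depth``.

    Lineages shallower than ``depth`` keep their own (deepest labeled) prefix,
    so probability mass is conserved exactly.
    """
    agg: dict[Lineage, float] = defaultdict(float)
    for lineage, p in probs.items():
        agg[lineage.truncate(depth)] += p
    return dict(agg)


def assign_with_confidence(
    probs: Mapping[Lineage, float],
    confidence: float,
    rng: np.random.Generator | int | Sequence[int] = 0,
    read_id: str = "",
) -> Assignment:
    """Turn one read's class probabilities into a possibly truncated lineage.

    Parameters
    ----------
    probs
        Species-level class probabilities (non-negative, summing to 1).
    confidence
        Threshold in [0, 1); the winning aggregate must strictly exceed it.
    rng
        Seed or generator for breaking exact-maximum ties uniformly at random.
    """
    if not 0.0 <= confidence < 1.0:
        raise ValueError("confidence must lie in [0, 1)")
    if not probs:
        raise ValueError("empty probability vector")
    values = np.fromiter(probs.values(), dtype=float)
    if (values < -1e-12).any():
        raise ValueError("negative class probability")
    if abs(values.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"class probabilities sum to {values.sum()}, not 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    max_depth = max(lin.depth for lin in probs)
    for depth in range(max_depth, 0, -1):
        agg = aggregate_at_depth(probs, depth)
        best = max(agg.values())
        if best > confidence:
            candidates = sorted(l for l, p in agg.items() if p >= best - _TIE_TOL)
            winner = candidates[0] if len(candidates) == 1 else candidates[
                rng.integers(len(candidates))
            ]
            return Assignment(read_id, winner, float(agg[winner]))
    return Assignment(read_id, Lineage(), 0.0)


class RankConfidenceClassifierMixin:
    """Shared ``classify`` driver for models exposing per-read probabilities.

    Implementers provide ``class_probabilities(sequence) -> {Lineage: prob}``.
    Tie-break randomness is seeded per read (seed, read index) so that a
    read's assignment does not depend on how many other reads were classified
    before it.
    """

    def class_probabilities(self, sequence: str) -> dict[Lineage, float]:
        raise NotImplementedError

    def classify(
        self, reads: ReadSet, confidence: float = 0.7, seed: int = 0
    ) -> list[Assignment]:
        out = []
        for i, (rid, seq) in enumerate(reads.reads):
            probs = self.class_probabilities(seq)
            rng = np.random.default_rng([seed, i])
            out.append(assign_with_confidence(probs, confidence, rng, read_id=rid))
        return out
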