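"""Per-rank classification metrics, multiclass MCC, cross-validation, and
paired classifier comparison statistics.

Metrics are micro-averaged over reads, optionally weighted by community
abundance, which matches evaluation of composition-driven communities: a
read from an abundant species counts proportionally more.  At a chosen rank
r, a read is a true positive when it is assigned at depth >= r with the
correct r-rank prefix; a wrong deep assignment contributes to both the
false positives and the false negatives, and an assignment truncated above
r contributes a false negative only.
"""
from __future__ import annotations

import warnings
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .class_weights import ClassWeights
from .perfect import PerfectClassifier
from .refdb_io import Assignment, Lineage, ReadSet, ReferenceDB, RANK_NAMES

#: sentinel predicted category for reads not assigned at the evaluation rank
TRUNCATED_CATEGORY = "unassigned/truncated"


def _rank_depth(rank: str | int) -> int:
    if isinstance(rank, int):
        if not 1 <= rank <= len(RANK_NAMES):
            raise ValueError(f"rank index {rank} out of range")
        return rank
    try:
        return RANK_NAMES.index(rank) + 1
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}") from None


@dataclass
class RankMetrics:
    rank: str
    precision: float
    recall: float
    f_measure: float
    tp: float
    fp: float
    fn: float
    flags: list[str] = field(default_factory=list)


def evaluate_assignments(
    assignments: Sequence[Assignment],
    truth: Mapping[str, Lineage],
    rank: str | int = "species",
    read_weights: Mapping[str, float] | None = None,
) -> RankMetrics:
    """Micro-averaged precision/recall/F at one rank, optionally read-weighted."""
    depth = _rank_depth(rank)
    if not any(l.depth >= depth for l in truth.values()):
        raise ValueError(f"no truth lineage carries a label at rank depth {depth}")
    tp = fp = fn = 0.0
    for a in assignments:
        if a.read_id not in truth:
            raise ValueError(f"no truth for read {a.read_id!r}")
        w = 1.0 if read_weights is None else read_weights[a.read_id]
        t = truth[a.read_id]
        assigned_here = a.lineage.depth >= depth
        correct = assigned_here and t.matches_at(a.lineage, depth)
        if correct:
            tp += w
        else:
            if assigned_here:
                fp += w
            if t.depth >= depth:
                fn += w
    flags: list[str] = []
    if tp + fp == 0:
        precision = 0.0
        flags.append("no-reads-assigned-at-rank")
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    rank_name = RANK_NAMES[depth - 1]
    return RankMetrics(rank_name, precision, recall, f, tp, fp, fn, flags)


def species_confusion(
    assignments: Sequence[Assignment],
    truth: Mapping[str, Lineage],
    read_weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, list]:
    """Full species-level confusion matrix with an unassigned/truncated
    predicted category (kept square so MCC applies directly)."""
    classes = sorted({l for l in truth.values()})
    labels: list = classes + [TRUNCATED_CATEGORY]
    index = {c: i for i, c in enumerate(classes)}
    M = np.zeros((len(labels), len(labels)))
    trunc = len(labels) - 1
    for a in assignments:
        t = truth[a.read_id]
        w = 1.0 if read_weights is None else read_weights[a.read_id]
        i = index.get(t, trunc)
        j = index.get(a.lineage, trunc)
        M[i, j] += w
    return M, labels


def mcc_score(confusion: np.ndarray) -> float:
    """Multiclass Matthews correlation coefficient in covariance form.

    MCC = (c*s - sum_k t_k p_k) / sqrt((s^2 - sum p_k^2)(s^2 - sum t_k^2))
    with c the trace, s the total, t (p) the row (column) sums.  Degenerate
    matrices (a single non-empty row or column) have zero denominator and
    are reported as 0 with a warning.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("confusion matrix must be square")
    s = M.sum()
    if s <= 0:
        raise ValueError("empty confusion matrix")
    c = np.trace(M)
    t = M.sum(axis=1)
    p = M.sum(axis=0)
    denom2 = (s**2 - (p**2).sum()) * (s**2 - (t**2).sum())
    if denom2 <= 0:
        warnings.warn("degenerate confusion matrix; MCC reported as 0", stacklevel=2)
        return 0.0
    return float((c * s - t @ p) / np.sqrt(denom2))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    fold: int
    metrics: dict[str, RankMetrics]
    mcc: float
    n_test: int


def _deepest_trainable(truth: Lineage, train_ancestors: set[Lineage]) -> Lineage:
    for d in range(truth.depth, 0, -1):
        if truth.truncate(d) in train_ancestors:
            return truth.truncate(d)
    return Lineage()


def _restrict_weights(weights: ClassWeights, classes: set[Lineage]) -> ClassWeights:
    sub = {c: weights[c] for c in classes}
    total = sum(sub.values())
    return ClassWeights({c: w / total for c, w in sub.items()}, mode=weights.mode)


def crossvalidate(
    refdb: ReferenceDB,
    weights: ClassWeights,
    classifier_factory: Callable[[], object],
    folds: int = 5,
    confidence: float = 0.7,
    seed: int = 0,
    read_length: int | None = None,
    ranks: Sequence[str] = ("genus", "species"),
    weighted_reads: bool = True,
) -> list[FoldResult]:
    """Community-weighted cross-validation over unique reference sequences.

    Unique sequences are partitioned into ``folds`` folds, stratified by
    species where a species has at least ``folds`` sequences.  Per fold the
    classifier is trained on the complement (with the weight table restricted
    and renormalized to the training species) and tested on the held-out
    sequences, each test read weighted by its species' community weight.
    Truth for a held-out read whose species is absent from training is
    truncated to its deepest ancestor present in training before scoring.

    A :class:`~ampliclass.perfect.PerfectClassifier` is trained in-sample on
    the full reference (its defining contract) but scored on the same frozen
    folds, mirroring how the ceiling is compared against trained classifiers.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    weights.check_bound(refdb)

    # unique sequences, stratified by (first) species
    by_seq: dict[str, list[str]] = {}
    for rid in refdb.ids():
        by_seq.setdefault(refdb.records[rid].sequence, []).append(rid)
    seqs = sorted(by_seq)
    rng = np.random.default_rng(seed)

    strata: dict[Lineage, list[str]] = {}
    for s in seqs:
        lin = min(refdb.records[r].lineage for r in by_seq[s])
        strata.setdefault(lin, []).append(s)
    fold_of: dict[str, int] = {}
    for lin in sorted(strata):
        members = strata[lin]
        rng.shuffle(members)
        offset = int(rng.integers(folds))
        for i, s in enumerate(members):
            fold_of[s] = (offset + i) % folds

    results: list[FoldResult] = []
    for f in range(folds):
        test_seqs = [s for s in seqs if fold_of[s] == f]
        train_ids = [r for s in seqs if fold_of[s] != f for r in by_seq[s]]
        if not test_seqs or not train_ids:
            raise ValueError(f"fold {f} is empty; reduce the number of folds")
        clf = classifier_factory()
        in_sample = isinstance(clf, PerfectClassifier)
        if in_sample:
            clf.fit(refdb, weights if weights.mode != "uniform" else None)
            train_classes = set(refdb.species_set())
        else:
            train_db = refdb.subset(train_ids)
            clf.fit(train_db, _restrict_weights(weights, set(train_db.species_set())))
            train_classes = set(train_db.species_set())
        ancestors = {
            c.truncate(d) for c in train_classes for d in range(1, c.depth + 1)
        }

        reads: list[tuple[str, str]] = []
        truth: dict[str, Lineage] = {}
        rweights: dict[str, float] = {}
        species_test_counts: dict[Lineage, int] = {}
        for s in test_seqs:
            lin = min(refdb.records[r].lineage for r in by_seq[s])
            species_test_counts[lin] = species_test_counts.get(lin, 0) + 1
        for s in test_seqs:
            rid = by_seq[s][0]
            seq = s if read_length is None else s[:read_length]
            if read_length is not None and len(s) < read_length:
                continue
            lin = min(refdb.records[r].lineage for r in by_seq[s])
            reads.append((rid, seq))
            truth[rid] = _deepest_trainable(lin, ancestors)
            rweights[rid] = weights[lin] / species_test_counts[lin]
        readset = ReadSet(reads, truth)
        assignments = clf.classify(readset, confidence=confidence, seed=seed + f)
        rw = rweights if weighted_reads else None
        metrics = {
            r: evaluate_assignments(assignments, truth, rank=r, read_weights=rw)
            for r in ranks
        }
        M, _ = species_confusion(assignments, truth, read_weights=rw)
        results.append(FoldResult(f, metrics, mcc_score(M), len(reads)))
    return results


# ---------------------------------------------------------------------------
# paired comparison statistics
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    name_a: str
    name_b: str
    mode: str
    statistic: float
    p_raw: float
    p_adjusted: float
    flags: list[str] = field(default_factory=list)


def compare_classifiers(
    comparisons: Sequence[tuple[str, str, Sequence[float], Sequence[float]]],
    mode: str = "signed-rank",
    alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Two-tailed Wilcoxon tests with family-wise Hommel adjustment.

    ``signed-rank`` pairs the two score vectors (equal length required);
    ``rank-sum`` compares independent samples (used when the underlying
    sample sets differ).  All comparisons submitted together form one
    family for the Hommel correction; significance is judged at ``alpha``.
    """
    if mode not in ("signed-rank", "rank-sum"):
        raise ValueError("mode must be 'signed-rank' or 'rank-sum'")
    raw: list[tuple[float, float, list[str]]] = []
    for name_a, name_b, a, b in comparisons:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need at least 2 observations per group")
        flags: list[str] = []
        if mode == "signed-rank":
            if len(a) != len(b):
                raise ValueError("signed-rank mode requires paired, equal-length scores")
            if np.all(a == b):
                raw.append((0.0, 1.0, ["all-zero-differences"]))
                continue
            stat, p = stats.wilcoxon(a, b, alternative="two-sided")
        else:
            stat, p = stats.ranksums(a, b, alternative="two-sided")
        raw.append((float(stat), float(p), flags))
    adjusted = multipletests([p for _, p, _ in raw], alpha=alpha, method="hommel")[1]
    return [
        ComparisonResult(c[0], c[1], mode, s, p, float(padj), flags)
        for c, (s, p, flags), padj in zip(comparisons, raw, adjusted)
    ]
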