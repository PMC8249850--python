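"""K-mer feature extraction: unordered count bags and ordered sentences.

Both the naive Bayes and forest classifiers consume a bag of overlapping
k-mers (default k=7); the convolutional classifier consumes the ordered
"sentence" of overlapping k-mers, whose length for an L nt read is exactly
L - k + 1 (144 tokens for a 150 nt read at k=7).

Ambiguity handling: windows containing any character outside {A,C,G,T} are
skipped in bags and replaced by a reserved out-of-vocabulary token in
sentences, so sentence geometry is preserved.  IUPAC codes are never
expanded.
"""
from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Sequence

import numpy as np
from scipy import sparse

DEFAULT_K = 7

#: reserved out-of-vocabulary token for ambiguous windows
OOV_TOKEN = "<oov>"

_CLEAN = frozenset("ACGT")


def kmer_counts(sequence: str, k: int = DEFAULT_K) -> Counter:
    """Bag of overlapping k-mer counts; ambiguous windows are skipped.

    A sequence shorter than k yields an empty bag (not an error).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sequence = sequence.upper()
    bag: Counter = Counter()
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        if _CLEAN.issuperset(window):
            bag[window] += 1
    return bag


def kmer_sentence(sequence: str, k: int = DEFAULT_K) -> list[str]:
    """Ordered overlapping k-mer tokens; ambiguous windows become OOV_TOKEN.

    Raises for sequences shorter than k — the sentence contract requires a
    fixed geometry of L - k + 1 tokens.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sequence = sequence.upper()
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} is shorter than k={k}")
    return [
        sequence[i : i + k] if _CLEAN.issuperset(sequence[i : i + k]) else OOV_TOKEN
        for i in range(len(sequence) - k + 1)
    ]


def build_vocabulary(bags: Iterable[Counter]) -> dict[str, int]:
    """Sorted k-mer -> column index mapping over all observed k-mers."""
    vocab = sorted({kmer for bag in bags for kmer in bag})
    return {kmer: i for i, kmer in enumerate(vocab)}


def bags_to_matrix(
    bags: Sequence[Counter], vocabulary: dict[str, int]
) -> sparse.csr_matrix:
    """Stack bags into a sparse count matrix; out-of-vocabulary k-mers are dropped.

    Dropping is only appropriate for models (e.g. the forest) that carry no
    OOV column; the naive Bayes model routes unseen k-mers explicitly.
    """
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for r, bag in enumerate(bags):
        for kmer, count in bag.items():
            j = vocabulary.get(kmer)
            if j is not None:
                rows.append(r)
                cols.append(j)
                vals.append(count)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(bags), len(vocabulary)), dtype=np.float64
    )
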