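"""Continuous-bag-of-words (word2vec CBOW) embedding of k-mer sentences.

Each reference read is rendered as an ordered sentence of overlapping
k-mers; CBOW learns a dense vector per k-mer token by predicting each token
from the mean of its context-window neighbours, trained by stochastic
gradient descent with negative sampling against a unigram^0.75 noise
distribution.  Defaults follow the benchmark convention: 300-dimensional
vectors and a symmetric window of 5 tokens.

Training is single-threaded and fully deterministic under a fixed seed.
The embedding is trained on reference sentences only, never on query
reads, to avoid test leakage.
"""
from __future__ import annotations

from collections import Counter
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .kmer_features import OOV_TOKEN

DEFAULT_DIM = 300
DEFAULT_WINDOW = 5


@dataclass
class EmbeddingTable:
    """Token -> dense vector lookup with a guaranteed OOV row."""

    tokens: list[str]
    vectors: np.ndarray  # (V, dim)
    k: int
    window: int
    corpus: str = ""
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.tokens):
            raise ValueError("token list and vector matrix disagree")
        if OOV_TOKEN not in self.tokens:
            raise ValueError("embedding table must carry the OOV token")
        self.index = {t: i for i, t in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return int(self.vectors.shape[1])

    def vector(self, token: str) -> np.ndarray:
        if token != OOV_TOKEN and len(token) != self.k:
            raise ValueError(
                f"token {token!r} has length {len(token)}, table expects k={self.k}"
            )
        return self.vectors[self.index.get(token, self.index[OOV_TOKEN])]


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


def train_embedding(
    sentences: Sequence[Sequence[str]],
    dim: int = DEFAULT_DIM,
    window: int = DEFAULT_WINDOW,
    epochs: int = 5,
    negative: int = 5,
    lr: float = 0.025,
    min_lr: float = 1e-4,
    seed: int = 0,
) -> EmbeddingTable:
    """Train CBOW vectors with negative sampling on k-mer sentences.

    Returns a table over every token observed in the corpus plus the OOV
    token (which receives a zero vector if it never occurred, so all-OOV
    reads embed as identical rows).
    """
    sentences = [list(s) for s in sentences if s]
    if not sentences:
        raise ValueError("empty training corpus")
    k = next(len(t) for s in sentences for t in s if t != OOV_TOKEN)

    counts = Counter(t for s in sentences for t in s)
    tokens = sorted(counts)
    if OOV_TOKEN not in counts:
        tokens.append(OOV_TOKEN)
    index = {t: i for i, t in enumerate(tokens)}
    V = len(tokens)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim  # input (projection) vectors
    W_out = np.zeros((V, dim))  # output (context-prediction) vectors

    # unigram^0.75 noise distribution, the standard negative-sampling choice
    freq = np.array([counts.get(t, 0) for t in tokens], dtype=float)
    noise = freq**0.75
    if noise.sum() == 0:
        noise[:] = 1.0
    noise /= noise.sum()

    encoded = [np.array([index[t] for t in s], dtype=np.int64) for s in sentences]
    total_positions = sum(len(s) for s in encoded)
    step = 0
    total_steps = max(1, epochs * total_positions)

    for _ in range(epochs):
        for sent in encoded:
            L = len(sent)
            for pos in range(L):
                alpha = max(min_lr, lr * (1.0 - step / total_steps))
                step += 1
                lo, hi = max(0, pos - window), min(L, pos + window + 1)
                ctx = np.concatenate([sent[lo:pos], sent[pos + 1 : hi]])
                if ctx.size == 0:
                    continue
                center = sent[pos]
                h = W_in[ctx].mean(axis=0)
                err = np.zeros(dim)
                negs = rng.choice(V, size=negative, p=noise)
                for target, label in [(center, 1.0)] + [(n, 0.0) for n in negs]:
                    if label == 0.0 and target == center:
                        continue
                    f = _sigmoid(float(h @ W_out[target]))
                    g = alpha * (label - f)
                    err += g * W_out[target]
                    W_out[target] += g * h
                W_in[ctx] += err / ctx.size

    if counts.get(OOV_TOKEN, 0) == 0:
        W_in[index[OOV_TOKEN]] = 0.0
    return EmbeddingTable(
        tokens=tokens,
        vectors=W_in,
        k=k,
        window=window,
        corpus=f"{len(sentences)} sentences, {total_positions} tokens",
    )


def embed_read(sentence: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Stack token vectors into a (len(sentence), dim) matrix; OOV rows use
    the OOV vector."""
    if not sentence:
        raise ValueError("empty sentence")
    return np.stack([table.vector(t) for t in sentence])
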