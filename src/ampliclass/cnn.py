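"""One-dimensional convolutional classifiers over embedded k-mer sentences.

Two architectures are provided:

* **Architecture I** — input is the CBOW-embedded sentence of overlapping
  k-mers (144 x dim for a 150 nt read at k=7): a single 1-D convolution
  (``filters`` filters of width ``kernel_size``) over the sequence axis,
  ReLU, global max pooling, then a dense softmax over species classes.
* **Architecture II** — the same stack, but the input is the per-nucleotide
  one-hot encoding of the read (150 x 4) instead of the embedding.

Global max pooling makes the pre-softmax features invariant to where along
the read a motif occurs.  Training minimizes class-weighted cross-entropy
(instance weights proportional to the taxonomic class weight) with the Adam
optimizer; everything is plain numpy, single-threaded, and deterministic
under a fixed seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .class_weights import ClassWeights
from .embedding import EmbeddingTable, embed_read, train_embedding
from .kmer_features import DEFAULT_K, kmer_sentence
from .rank_confidence import RankConfidenceClassifierMixin
from .refdb_io import Lineage, ReferenceDB

#: the benchmark's CNN hyperparameter grid
CNN_GRID = {
    "filters": (64, 128, 256, 512),
    "kernel_size": (3, 5, 7),
    "confidence": (0.5, 0.7, 0.95),
    "epochs": (5, 10),
}

_ONE_HOT = {"A": 0, "C": 1, "G": 2, "T": 3}


def one_hot_read(sequence: str) -> np.ndarray:
    """(L, 4) one-hot encoding; ambiguous bases become all-zero rows."""
    X = np.zeros((len(sequence), 4))
    for i, base in enumerate(sequence.upper()):
        j = _ONE_HOT.get(base)
        if j is not None:
            X[i, j] = 1.0
    return X


@dataclass
class CnnConfig:
    architecture: str = "I"  # "I" (embedded sentences) | "II" (one-hot)
    filters: int = 64
    kernel_size: int = 3
    epochs: int = 5
    batch_size: int = 128
    lr: float = 1e-2  # suits the short (5-10 epoch) training budgets used here
    embedding_dim: int = 300
    embedding_window: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ("I", "II"):
            raise ValueError("architecture must be 'I' or 'II'")
        if min(self.filters, self.kernel_size, self.epochs, self.batch_size) < 1:
            raise ValueError("filters, kernel_size, epochs, batch_size must be positive")


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float) -> None:
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray], b1: float = 0.9, b2: float = 0.999) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + 1e-8)


class ConvNetClassifier(RankConfidenceClassifierMixin):
    """Conv -> ReLU -> global max pool -> softmax taxonomic classifier."""

    def __init__(
        self,
        config: CnnConfig | None = None,
        k: int = DEFAULT_K,
        read_length: int = 150,
        embedding: EmbeddingTable | None = None,
    ) -> None:
        self.config = config or CnnConfig()
        self.k = int(k)
        self.read_length = int(read_length)
        self.embedding = embedding
        self.classes_: list[Lineage] = []
        self.W_conv: np.ndarray | None = None  # (kernel*channels, filters)
        self.b_conv: np.ndarray | None = None
        self.W_dense: np.ndarray | None = None  # (filters, n_classes)
        self.b_dense: np.ndarray | None = None
        self.input_scale_: float = 1.0  # fixed at fit time: unit-RMS inputs
        self.history_: list[float] = []

    # -- geometry -----------------------------------------------------------
    @property
    def n_channels(self) -> int:
        if self.config.architecture == "II":
            return 4
        if self.embedding is None:
            raise RuntimeError("architecture I needs an embedding table")
        return self.embedding.dim

    def _encode(self, sequence: str) -> np.ndarray:
        if len(sequence) < self.read_length:
            raise ValueError(
                f"read of length {len(sequence)} shorter than the "
                f"{self.read_length} nt input geometry"
            )
        sequence = sequence[: self.read_length].upper()
        if self.config.architecture == "II":
            return one_hot_read(sequence)
        return embed_read(kmer_sentence(sequence, self.k), self.embedding)

    # -- forward / backward -------------------------------------------------
    def _patches(self, X: np.ndarray) -> np.ndarray:
        w = self.config.kernel_size
        # (N, T', C, w) -> (N, T', w*C) with time-major window layout
        view = np.lib.stride_tricks.sliding_window_view(X, w, axis=1)
        return np.ascontiguousarray(view.transpose(0, 1, 3, 2)).reshape(
            X.shape[0], X.shape[1] - w + 1, -1
        )

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, dict]:
        """Logits for a batch of encoded reads (N, T, C); cache for backprop."""
        P = self._patches(X)
        Z = P @ self.W_conv + self.b_conv
        A = np.maximum(Z, 0.0)
        arg = A.argmax(axis=1)  # (N, F)
        pooled = np.take_along_axis(A, arg[:, None, :], axis=1)[:, 0, :]
        logits = pooled @ self.W_dense + self.b_dense
        return logits, {"P": P, "Z": Z, "arg": arg, "pooled": pooled}

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    # -- training -----------------------------------------------------------
    def fit(self, refdb: ReferenceDB, weights: ClassWeights) -> "ConvNetClassifier":
        weights.check_bound(refdb)
        cfg = self.config
        self.classes_ = refdb.species_set()
        if len(self.classes_) < 2:
            raise ValueError("CNN training requires at least 2 classes")
        class_index = {c: i for i, c in enumerate(self.classes_)}

        usable = [
            (i, r)
            for i, r in refdb.records.items()
            if len(r.sequence) >= self.read_length
        ]
        if not usable:
            raise ValueError(f"no reference sequence reaches {self.read_length} nt")

        if cfg.architecture == "I" and self.embedding is None:
            sentences = [
                kmer_sentence(r.sequence[: self.read_length], self.k)
                for _, r in usable
            ]
            self.embedding = train_embedding(
                sentences,
                dim=cfg.embedding_dim,
                window=cfg.embedding_window,
                seed=cfg.seed,
            )

        X = np.stack([self._encode(r.sequence) for _, r in usable])
        # normalize to unit RMS so the optimizer sees a scale-free input
        # regardless of embedding vector magnitudes
        rms = float(np.sqrt((X**2).mean()))
        self.input_scale_ = 1.0 / rms if rms > 0 else 1.0
        X *= self.input_scale_
        y = np.array([class_index[r.lineage] for _, r in usable])
        n_per_class = np.bincount(y, minlength=len(self.classes_)).astype(float)
        w_class = np.array([weights[c] for c in self.classes_])
        inst_w = (w_class / np.maximum(n_per_class, 1.0))[y]
        inst_w *= len(inst_w) / inst_w.sum()  # mean 1 keeps the lr scale sane

        rng = np.random.default_rng(cfg.seed)
        C_in = X.shape[2]
        fan_in = cfg.kernel_size * C_in
        self.W_conv = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_in, cfg.filters))
        self.b_conv = np.zeros(cfg.filters)
        limit = np.sqrt(6.0 / (cfg.filters + len(self.classes_)))
        self.W_dense = rng.uniform(-limit, limit, (cfg.filters, len(self.classes_)))
        self.b_dense = np.zeros(len(self.classes_))

        opt = _Adam([self.W_conv, self.b_conv, self.W_dense, self.b_dense], cfg.lr)
        n = len(y)
        self.history_ = []
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits, cache = self.forward(X[idx])
                probs = self._softmax(logits)
                wb = inst_w[idx]
                p_true = np.clip(probs[np.arange(len(idx)), y[idx]], 1e-12, None)
                epoch_loss += float((wb * -np.log(p_true)).sum())

                dlogits = probs.copy()
                dlogits[np.arange(len(idx)), y[idx]] -= 1.0
                dlogits *= (wb / wb.sum())[:, None]
                dWd = cache["pooled"].T @ dlogits
                dbd = dlogits.sum(axis=0)
                dpooled = dlogits @ self.W_dense.T
                dA = np.zeros_like(cache["Z"])
                np.put_along_axis(dA, cache["arg"][:, None, :], dpooled[:, None, :], axis=1)
                dZ = dA * (cache["Z"] > 0)
                F = self.config.filters
                dWc = cache["P"].reshape(-1, cache["P"].shape[2]).T @ dZ.reshape(-1, F)
                dbc = dZ.sum(axis=(0, 1))
                opt.step([dWc, dbc, dWd, dbd])
            self.history_.append(epoch_loss / inst_w.sum())
        return self

    # -- inference ----------------------------------------------------------
    def class_probabilities(self, sequence: str) -> dict[Lineage, float]:
        if self.W_conv is None:
            raise RuntimeError("model is not fitted")
        X = self._encode(sequence)[None, :, :] * self.input_scale_
        if X.shape[2] != self.W_conv.shape[0] // self.config.kernel_size:
            raise ValueError("input channel count does not match the trained network")
        logits, _ = self.forward(X)
        return dict(zip(self.classes_, self._softmax(logits)[0]))


def train_cnn(
    refdb: ReferenceDB,
    weights: ClassWeights,
    config: CnnConfig | None = None,
    k: int = DEFAULT_K,
    read_length: int = 150,
    embedding: EmbeddingTable | None = None,
) -> ConvNetClassifier:
    return ConvNetClassifier(
        config=config, k=k, read_length=read_length, embedding=embedding
    ).fit(refdb, weights)
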