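"""Deterministic single-archive model serialization.

A model archive is a zip holding ``meta.json`` plus one ``.npy`` member per
array (and a pickle member for the tree ensemble, whose structure is not
array-shaped).  Zip member timestamps are fixed so that re-running a fit
with the same seed produces a byte-identical archive.
"""
from __future__ import annotations

import io
import json
import pickle
import zipfile
from pathlib import Path

import numpy as np

from .class_weights import ClassWeights
from .cnn import CnnConfig, ConvNetClassifier
from .embedding import EmbeddingTable
from .naive_bayes import WeightedNaiveBayes
from .random_forest import ForestConfig, KmerForestClassifier
from .refdb_io import Lineage, parse_lineage

_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp -> reproducible bytes


def _write_member(zf: zipfile.ZipFile, name: str, payload: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_EPOCH)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, payload)


def _array_bytes(arr: np.ndarray) -> bytes:
    buf = io.BytesIO()
    np.save(buf, arr)
    return buf.getvalue()


def save_model(model, path: str | Path) -> None:
    meta: dict = {"classes": [str(c) for c in model.classes_]}
    arrays: dict[str, np.ndarray] = {}
    blobs: dict[str, bytes] = {}
    if isinstance(model, WeightedNaiveBayes):
        meta.update(kind="nb", alpha=model.alpha, k=model.k,
                    vocabulary=list(model.vocabulary_))
        arrays["feature_log_prob"] = model.feature_log_prob_
        arrays["log_prior"] = model.log_prior_
    elif isinstance(model, KmerForestClassifier):
        cfg = model.config
        meta.update(
            kind="rf", k=model.k, vocabulary=list(model.vocabulary_),
            n_estimators=cfg.n_estimators, max_depth=cfg.max_depth,
            max_features=cfg.max_features, seed=cfg.seed,
        )
        blobs["forest.pkl"] = pickle.dumps(model._forest, protocol=4)
    elif isinstance(model, ConvNetClassifier):
        cfg = model.config
        meta.update(
            kind="cnn", k=model.k, read_length=model.read_length,
            architecture=cfg.architecture, filters=cfg.filters,
            kernel_size=cfg.kernel_size, epochs=cfg.epochs,
            batch_size=cfg.batch_size, lr=cfg.lr, seed=cfg.seed,
            embedding_dim=cfg.embedding_dim, embedding_window=cfg.embedding_window,
            input_scale=model.input_scale_,
        )
        arrays["W_conv"] = model.W_conv
        arrays["b_conv"] = model.b_conv
        arrays["W_dense"] = model.W_dense
        arrays["b_dense"] = model.b_dense
        if model.embedding is not None:
            meta["embedding_tokens"] = model.embedding.tokens
            meta["embedding_k"] = model.embedding.k
            arrays["embedding_vectors"] = model.embedding.vectors
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    with zipfile.ZipFile(path, "w") as zf:
        _write_member(zf, "meta.json", json.dumps(meta, sort_keys=True).encode())
        for name in sorted(arrays):
            _write_member(zf, f"{name}.npy", _array_bytes(arrays[name]))
        for name in sorted(blobs):
            _write_member(zf, name, blobs[name])


def load_model(path: str | Path):
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {
            n[:-4]: np.load(io.BytesIO(zf.read(n)))
            for n in zf.namelist()
            if n.endswith(".npy")
        }
        classes = [parse_lineage(c) for c in meta["classes"]]
        if meta["kind"] == "nb":
            m = WeightedNaiveBayes(alpha=meta["alpha"], k=meta["k"])
            m.classes_ = classes
            m.vocabulary_ = {w: j for j, w in enumerate(meta["vocabulary"])}
            m.feature_log_prob_ = arrays["feature_log_prob"]
            m.log_prior_ = arrays["log_prior"]
            return m
        if meta["kind"] == "rf":
            cfg = ForestConfig(
                n_estimators=meta["n_estimators"], max_depth=meta["max_depth"],
                max_features=meta["max_features"], seed=meta["seed"],
            )
            m = KmerForestClassifier(config=cfg, k=meta["k"])
            m.classes_ = classes
            m.vocabulary_ = {w: j for j, w in enumerate(meta["vocabulary"])}
            m._forest = pickle.loads(zf.read("forest.pkl"))
            return m
        if meta["kind"] == "cnn":
            cfg = CnnConfig(
                architecture=meta["architecture"], filters=meta["filters"],
                kernel_size=meta["kernel_size"], epochs=meta["epochs"],
                batch_size=meta["batch_size"], lr=meta["lr"], seed=meta["seed"],
                embedding_dim=meta["embedding_dim"],
                embedding_window=meta["embedding_window"],
            )
            table = None
            if "embedding_vectors" in arrays:
                table = EmbeddingTable(
                    tokens=meta["embedding_tokens"],
                    vectors=arrays["embedding_vectors"],
                    k=meta["embedding_k"],
                    window=meta["embedding_window"],
                )
            m = ConvNetClassifier(
                config=cfg, k=meta["k"], read_length=meta["read_length"],
                embedding=table,
            )
            m.classes_ = classes
            m.input_scale_ = meta["input_scale"]
            m.W_conv = arrays["W_conv"]
            m.b_conv = arrays["b_conv"]
            m.W_dense = arrays["W_dense"]
            m.b_dense = arrays["b_dense"]
            return m
    raise ValueError(f"unknown model kind {meta['kind']!r}")
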