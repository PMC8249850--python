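import numpy as np
import pytest

from ampliclass.class_weights import uniform_weights
from ampliclass.cnn import CnnConfig, ConvNetClassifier, one_hot_read, train_cnn
from ampliclass.evaluate import evaluate_assignments
from ampliclass.refdb_io import ReadSet, ReferenceDB, RefRecord

from conftest import full_lineage

A_CLASS = full_lineage("G1", "A")
B_CLASS = full_lineage("G2", "B")


def _motif_db(n_per_class=10, length=150, seed=0):
    """Two classes distinguished by a planted homopolymer motif in an
    otherwise random background."""
    rng = np.random.default_rng(seed)
    recs = {}
    for i in range(n_per_class):
        for cls, motif, tag in ((A_CLASS, "A" * 12, "a"), (B_CLASS, "C" * 12, "b")):
            bg = "".join(rng.choice(list("ACGT"), length))
            pos = int(rng.integers(20, length - 40))
            seq = bg[:pos] + motif + bg[pos + len(motif):]
            recs[f"{tag}{i}"] = RefRecord(seq[:length], cls)
    return ReferenceDB(recs)


def _micro_net():
    """1-filter, kernel-3, 2-class architecture-II network with fixed weights."""
    clf = ConvNetClassifier(
        config=CnnConfig(architecture="II", filters=1, kernel_size=3),
        read_length=10,
    )
    clf.classes_ = [A_CLASS, B_CLASS]
    rng = np.random.default_rng(0)
    clf.W_conv = rng.normal(size=(12, 1))  # 3 positions x 4 channels
    clf.b_conv = np.array([0.1])
    clf.W_dense = rng.normal(size=(1, 2))
    clf.b_dense = np.array([0.0, 0.2])
    return clf


def test_forward_pass_matches_hand_computation():
    """Conv + ReLU + global max pool + softmax recomputed with bare loops."""
    clf = _micro_net()
    seq = "ACGTTGCAAC"
    X = one_hot_read(seq)
    logits, _ = clf.forward(X[None])

    conv = []
    for t in range(len(seq) - 2):
        z = clf.b_conv[0]
        for dt in range(3):
            for ch in range(4):
                z += X[t + dt, ch] * clf.W_conv[dt * 4 + ch, 0]
        conv.append(max(z, 0.0))
    pooled = max(conv)
    expected = np.array(
        [pooled * clf.W_dense[0, 0] + 0.0, pooled * clf.W_dense[0, 1] + 0.2]
    )
    assert logits[0] == pytest.approx(expected, abs=1e-12)

    probs = clf.class_probabilities(seq)
    e = np.exp(expected - expected.max())
    assert list(probs.values()) == pytest.approx(e / e.sum(), abs=1e-12)


def test_global_max_pool_is_translation_invariant():
    """Moving a motif within a constant background leaves logits unchanged."""
    clf = _micro_net()
    clf.read_length = 150
    bg = "A" * 150
    logits = []
    for pos in (10, 50, 120):
        seq = bg[:pos] + "CGT" + bg[pos + 3:]
        l, _ = clf.forward(one_hot_read(seq[:150])[None])
        logits.append(l[0])
    assert np.abs(logits[0] - logits[1]).max() < 1e-4
    assert np.abs(logits[0] - logits[2]).max() < 1e-4


def test_output_is_simplex_per_read():
    db = _motif_db(n_per_class=4)
    cfg = CnnConfig(architecture="II", filters=4, kernel_size=3, epochs=2, seed=0)
    model = train_cnn(db, uniform_weights(db), cfg)
    for rec in list(db.records.values())[:4]:
        p = np.array(list(model.class_probabilities(rec.sequence).values()))
        assert p.min() >= 0
        assert p.sum() == pytest.approx(1.0, abs=1e-9)


def test_separable_motifs_reach_high_training_f():
    """Architecture I on a two-motif toy: training F >= 0.95, mean of 3 seeds."""
    db = _motif_db(n_per_class=10)
    w = uniform_weights(db)
    reads = ReadSet(
        [(i, r.sequence) for i, r in db.records.items()],
        {i: r.lineage for i, r in db.records.items()},
    )
    scores = []
    for seed in range(3):
        cfg = CnnConfig(architecture="I", filters=8, kernel_size=3, epochs=10,
                        embedding_dim=16, batch_size=8, seed=seed)
        model = train_cnn(db, w, cfg)
        assignments = model.classify(reads, confidence=0.0, seed=seed)
        scores.append(evaluate_assignments(assignments, reads.truth).f_measure)
    assert np.mean(scores) >= 0.95


def test_training_loss_decreases_on_toy():
    db = _motif_db(n_per_class=6)
    w = uniform_weights(db)
    first, fifth = [], []
    for seed in range(3):
        cfg = CnnConfig(architecture="II", filters=4, kernel_size=5, epochs=5,
                        batch_size=8, seed=seed)
        model = train_cnn(db, w, cfg)
        first.append(model.history_[0])
        fifth.append(model.history_[4])
    assert np.mean(fifth) <= np.mean(first)


def test_inference_is_deterministic():
    db = _motif_db(n_per_class=4)
    cfg = CnnConfig(architecture="II", filters=4, kernel_size=3, epochs=2, seed=1)
    model = train_cnn(db, uniform_weights(db), cfg)
    seq = next(iter(db.records.values())).sequence
    p1 = model.class_probabilities(seq)
    p2 = model.class_probabilities(seq)
    assert p1 == p2


def test_short_read_is_geometry_error():
    db = _motif_db(n_per_class=4)
    cfg = CnnConfig(architecture="II", filters=2, kernel_size=3, epochs=1, seed=0)
    model = train_cnn(db, uniform_weights(db), cfg)
    with pytest.raises(ValueError):
        model.class_probabilities("ACGT" * 10)


def test_fewer_than_two_classes_is_error():
    db = ReferenceDB({"r": RefRecord("A" * 150, A_CLASS)})
    with pytest.raises(ValueError):
        train_cnn(db, uniform_weights(db), CnnConfig(architecture="II"))
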