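from itertools import product

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import matthews_corrcoef

from ampliclass.class_weights import uniform_weights
from ampliclass.evaluate import (
    compare_classifiers,
    crossvalidate,
    evaluate_assignments,
    mcc_score,
    species_confusion,
)
from ampliclass.naive_bayes import WeightedNaiveBayes
from ampliclass.perfect import PerfectClassifier
from ampliclass.refdb_io import Assignment, Lineage

from conftest import full_lineage


def _assign(rid, lineage, conf=0.9):
    return Assignment(rid, lineage, conf)


S = [full_lineage("G1", f"s{i}") for i in range(4)]


class TestEvaluateAssignments:
    def test_all_correct_gives_ones(self):
        truth = {f"r{i}": S[i % 4] for i in range(8)}
        assignments = [_assign(r, t) for r, t in truth.items()]
        m = evaluate_assignments(assignments, truth)
        assert (m.precision, m.recall, m.f_measure) == (1.0, 1.0, 1.0)

    def test_all_unassigned_flags_precision(self):
        truth = {"r0": S[0], "r1": S[1]}
        assignments = [_assign(r, Lineage(), 0.0) for r in truth]
        m = evaluate_assignments(assignments, truth)
        assert m.recall == 0.0
        assert m.precision == 0.0
        assert "no-reads-assigned-at-rank" in m.flags

    def test_hand_tally_mixed_outcomes(self):
        """6 correct species, 2 wrong species, 2 truncated to genus:
        P=6/8, R=6/10, F=2PR/(P+R)."""
        truth = {f"r{i}": S[0] for i in range(10)}
        assignments = (
            [_assign(f"r{i}", S[0]) for i in range(6)]
            + [_assign(f"r{i}", S[1]) for i in range(6, 8)]
            + [_assign(f"r{i}", S[0].truncate(6)) for i in range(8, 10)]
        )
        m = evaluate_assignments(assignments, truth)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f_measure == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_genus_rank_counts_truncated_assignment(self):
        truth = {"r0": S[0]}
        m = evaluate_assignments([_assign("r0", S[0].truncate(6))], truth, rank="genus")
        assert m.f_measure == 1.0

    def test_uniform_weights_match_unweighted(self):
        truth = {f"r{i}": S[i % 2] for i in range(6)}
        assignments = [_assign(r, S[0]) for r in truth]
        unweighted = evaluate_assignments(assignments, truth)
        weighted = evaluate_assignments(
            assignments, truth, read_weights={r: 1.0 for r in truth}
        )
        assert (weighted.precision, weighted.recall) == (
            unweighted.precision,
            unweighted.recall,
        )

    def test_rank_deeper_than_truth_is_error(self):
        truth = {"r0": S[0].truncate(2)}
        with pytest.raises(ValueError):
            evaluate_assignments([_assign("r0", S[0])], truth, rank="species")


class TestMcc:
    def test_diagonal_matrix_is_one(self):
        assert mcc_score(np.diag([3, 5, 2])) == pytest.approx(1.0)

    def test_uniform_matrix_is_zero(self):
        assert mcc_score(np.full((3, 3), 4.0)) == pytest.approx(0.0)

    def test_degenerate_matrix_reported_as_zero(self):
        M = np.zeros((3, 3))
        M[1, 1] = 7
        with pytest.warns(UserWarning, match="degenerate"):
            assert mcc_score(M) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_sklearn(self, seed):
        """Covariance-form MCC equals sklearn's on label vectors realizing
        the same confusion matrix."""
        rng = np.random.default_rng(seed)
        M = rng.integers(0, 6, size=(3, 3))
        M[0, 0] += 1  # ensure non-degenerate
        y_true, y_pred = [], []
        for i, j in product(range(3), range(3)):
            y_true += [i] * M[i, j]
            y_pred += [j] * M[i, j]
        expected = matthews_corrcoef(y_true, y_pred)
        assert mcc_score(M.astype(float)) == pytest.approx(expected, abs=1e-12)


class TestConfusion:
    def test_truncated_predictions_fall_in_sentinel_column(self):
        truth = {"r0": S[0], "r1": S[1]}
        assignments = [_assign("r0", S[0]), _assign("r1", S[1].truncate(6))]
        M, labels = species_confusion(assignments, truth)
        assert labels[-1] == "unassigned/truncated"
        assert M[0, 0] == 1
        assert M[1, -1] == 1


class TestCrossvalidate:
    def test_five_folds_each_sequence_tested_once(self, small_synth):
        _, refdb, _, _ = small_synth
        w = uniform_weights(refdb)
        results = crossvalidate(refdb, w, WeightedNaiveBayes, folds=5, seed=3)
        assert len(results) == 5
        n_unique = len({r.sequence for r in refdb.records.values()})
        assert sum(r.n_test for r in results) == n_unique

    def test_perfect_classifier_scores_one_on_unique_fixture(self, small_synth):
        _, refdb, _, _ = small_synth
        w = uniform_weights(refdb)
        results = crossvalidate(refdb, w, PerfectClassifier, folds=2, seed=1)
        for r in results:
            assert r.metrics["species"].f_measure == pytest.approx(1.0)

    def test_fold_assignment_deterministic(self, small_synth):
        _, refdb, _, _ = small_synth
        w = uniform_weights(refdb)
        r1 = crossvalidate(refdb, w, WeightedNaiveBayes, folds=3, seed=7)
        r2 = crossvalidate(refdb, w, WeightedNaiveBayes, folds=3, seed=7)
        assert [f.metrics["species"].f_measure for f in r1] == [
            f.metrics["species"].f_measure for f in r2
        ]

    def test_too_few_folds_is_error(self, small_synth):
        _, refdb, _, _ = small_synth
        with pytest.raises(ValueError):
            crossvalidate(refdb, uniform_weights(refdb), WeightedNaiveBayes, folds=1)


def exact_signed_rank_p(a, b):
    """Two-sided exact Wilcoxon signed-rank p by enumerating sign vectors."""
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in product([0, 1], repeat=len(d)):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.array(dist)
    return min(1.0, 2 * min((dist <= w_obs).mean(), (dist >= w_obs).mean()))


class TestCompareClassifiers:
    def test_identical_paired_samples_adjusted_p_is_one(self):
        a = [0.5, 0.6, 0.7, 0.8]
        [res] = compare_classifiers([("x", "y", a, a)])
        assert res.p_adjusted == 1.0
        assert "all-zero-differences" in res.flags

    def test_single_comparison_hommel_is_identity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = a + rng.normal(0.5, 0.5, 10)
        [res] = compare_classifiers([("x", "y", a, b)])
        assert res.p_adjusted == pytest.approx(res.p_raw)

    @pytest.mark.parametrize("seed", range(4))
    def test_small_sample_signed_rank_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 11))
        a = rng.normal(0, 1, n)
        b = a + rng.normal(0.4, 1.0, n)
        [res] = compare_classifiers([("x", "y", a, b)])
        assert res.p_raw == pytest.approx(exact_signed_rank_p(a, b), abs=1e-12)

    def test_rank_sum_mode_for_unpaired_samples(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 12)
        b = rng.normal(2, 1, 15)
        [res] = compare_classifiers([("x", "y", a, b)], mode="rank-sum")
        assert res.p_raw < 0.01

    def test_hommel_adjustment_is_monotone_family_wise(self):
        rng = np.random.default_rng(3)
        comps = []
        for shift in (0.0, 0.3, 1.0):
            a = rng.normal(0, 1, 10)
            comps.append(("x", f"y{shift}", a, a + rng.normal(shift, 0.5, 10)))
        results = compare_classifiers(comps)
        for r in results:
            assert r.p_adjusted >= r.p_raw - 1e-15
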