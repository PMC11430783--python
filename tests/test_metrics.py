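"""Metric correctness against hand computations and naive oracles."""

import numpy as np
import pytest

from rnaloc import metrics as M
from rnaloc.metrics import EvaluationBatch

from conftest import random_batch


# ----------------------------------------------------------------- oracles
# Independent naive implementations, straight from the set-theoretic
# definitions, used only to cross-check the vectorized module.

def _oracle_ranks(scores):
    q = len(scores)
    order = sorted(range(q), key=lambda j: (-scores[j], j))
    ranks = [0] * q
    for pos, j in enumerate(order):
        ranks[j] = pos + 1
    return ranks


def _oracle_all(batch: EvaluationBatch):
    r, q = batch.r, batch.q
    acc = ap = cov = one = ham = 0.0
    rl_vals = []
    for i in range(r):
        T = {j for j in range(q) if batch.true[i, j]}
        P = {j for j in range(q) if batch.predicted[i, j]}
        s = batch.scores[i]
        ranks = _oracle_ranks(list(s))
        acc += len(T & P) / len(T | P)
        ap += sum(
            sum(1 for t2 in T if ranks[t2] <= ranks[t]) / ranks[t] for t in T
        ) / len(T)
        cov += max(ranks[t] for t in T) - 1
        top = min(range(q), key=lambda j: ranks[j])
        one += top not in T
        ham += len(T ^ P) / q
        F = set(range(q)) - T
        if F:
            bad = sum(1 for t in T for f in F if s[t] <= s[f])
            rl_vals.append(bad / (len(T) * len(F)))
    rl = sum(rl_vals) / len(rl_vals) if rl_vals else None
    return acc / r, ap / r, cov / r, one / r, rl, ham / r


# ------------------------------------------------------------- hand values

def test_rank_descending_hand_and_ties():
    assert M.rank_descending(np.array([0.2, 0.9, 0.6])).tolist() == [3, 1, 2]
    # all-equal scores: index tie-break gives identity ranks
    assert M.rank_descending(np.zeros(5)).tolist() == [1, 2, 3, 4, 5]


def test_rank_descending_is_permutation():
    rng = np.random.default_rng(0)
    scores = np.round(rng.random((50, 7)), 1)
    ranks = M.rank_descending(scores)
    expected = set(range(1, 8))
    assert all(set(row) == expected for row in ranks)


def test_worked_batch_exact(worked_batch):
    assert M.acc_exam(worked_batch) == pytest.approx(2 / 3, abs=1e-15)
    assert M.average_precision(worked_batch) == pytest.approx(19 / 24, abs=1e-15)
    assert M.coverage(worked_batch) == pytest.approx(1.5, abs=1e-15)
    assert M.one_error(worked_batch) == pytest.approx(0.5, abs=1e-15)
    rl, skipped = M.ranking_loss(worked_batch)
    assert rl == pytest.approx(0.5, abs=1e-15)
    assert skipped == 0
    assert M.hamming_loss(worked_batch) == pytest.approx(1 / 3, abs=1e-15)


def test_perfect_prediction_limits():
    true = np.array([[1, 1, 0, 0], [0, 0, 1, 0]], dtype=bool)
    scores = np.where(true, 0.9, 0.1)
    batch = EvaluationBatch(true, true, scores)
    report = M.evaluate_all(batch)
    assert report.acc_exam == 1.0
    assert report.average_precision == 1.0
    assert report.one_error == 0.0
    assert report.ranking_loss == 0.0
    assert report.hamming_loss == 0.0
    # coverage attains mean(|T_i|) - 1 when true labels fill the top ranks
    assert report.coverage == pytest.approx(np.mean([2, 1]) - 1)


def test_ranking_loss_tie_counts_as_violation():
    true = np.array([[1, 0]], dtype=bool)
    batch = EvaluationBatch(true, true, np.array([[0.5, 0.5]]))
    rl, _ = M.ranking_loss(batch)
    assert rl == 1.0


def test_ranking_loss_skips_full_universe_instances():
    true = np.array([[1, 1, 1], [1, 0, 0]], dtype=bool)
    scores = np.array([[0.5, 0.4, 0.3], [0.9, 0.1, 0.2]])
    rl, skipped = M.ranking_loss(EvaluationBatch(true, true, scores))
    assert skipped == 1
    assert rl == 0.0


def test_ranking_loss_undefined_when_all_full():
    true = np.ones((2, 3), dtype=bool)
    with pytest.raises(ValueError, match="undefined"):
        M.ranking_loss(EvaluationBatch(true, true, np.random.default_rng(0).random((2, 3))))


def test_empty_true_set_rejected():
    with pytest.raises(ValueError, match="non-empty"):
        EvaluationBatch(np.zeros((1, 3)), np.ones((1, 3)), np.ones((1, 3)))


# -------------------------------------------------------------- per-label

def test_per_label_hand_count():
    # 4 instances; L0 true in 2, hit once, no false positives
    true = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=bool)
    pred = np.array([[1, 0], [0, 0], [0, 1], [0, 1]], dtype=bool)
    scores = pred.astype(float)
    table = M.per_label_metrics(EvaluationBatch(true, pred, scores))
    assert table.loc["label_0", "recall"] == 0.5
    assert table.loc["label_0", "binary_accuracy"] == 0.75
    assert table.loc["label_1", "recall"] == 1.0


def test_per_label_binary_accuracy_matches_hamming():
    rng = np.random.default_rng(3)
    for _ in range(20):
        batch = random_batch(rng, r=int(rng.integers(2, 20)), q=int(rng.integers(2, 7)))
        table = M.per_label_metrics(batch)
        assert table["binary_accuracy"].mean() == pytest.approx(
            1.0 - M.hamming_loss(batch), abs=1e-12
        )


def test_per_label_zero_positive_label_is_nan():
    true = np.array([[1, 0]], dtype=bool)
    table = M.per_label_metrics(EvaluationBatch(true, true, true.astype(float)))
    assert np.isnan(table.loc["label_1", "recall"])


# ----------------------------------------------------------------- oracle

def test_all_metrics_match_oracle_on_random_batches():
    rng = np.random.default_rng(42)
    for _ in range(200):
        batch = random_batch(rng, r=int(rng.integers(1, 21)), q=int(rng.integers(2, 7)))
        o_acc, o_ap, o_cov, o_one, o_rl, o_ham = _oracle_all(batch)
        assert M.acc_exam(batch) == pytest.approx(o_acc, abs=1e-12)
        assert M.average_precision(batch) == pytest.approx(o_ap, abs=1e-12)
        assert M.coverage(batch) == pytest.approx(o_cov, abs=1e-12)
        assert M.one_error(batch) == pytest.approx(o_one, abs=1e-12)
        assert M.hamming_loss(batch) == pytest.approx(o_ham, abs=1e-12)
        if o_rl is not None:
            assert M.ranking_loss(batch)[0] == pytest.approx(o_rl, abs=1e-12)


def test_evaluate_all_report_ranges():
    rng = np.random.default_rng(7)
    for _ in range(50):
        batch = random_batch(rng, r=10, q=5)
        rep = M.evaluate_all(batch)
        for name in ("acc_exam", "average_precision", "one_error", "hamming_loss"):
            assert 0.0 <= getattr(rep, name) <= 1.0
        assert 0.0 <= rep.ranking_loss <= 1.0
        assert 0.0 <= rep.coverage <= batch.q - 1


def test_evaluate_all_worked_batch(worked_batch):
    rep = M.evaluate_all(worked_batch, labels=["L0", "L1", "L2"])
    assert (
        rep.acc_exam,
        rep.average_precision,
        rep.coverage,
        rep.one_error,
        rep.ranking_loss,
        rep.hamming_loss,
    ) == pytest.approx((2 / 3, 19 / 24, 1.5, 0.5, 0.5, 1 / 3), abs=1e-15)
    assert list(rep.per_label.index) == ["L0", "L1", "L2"]
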