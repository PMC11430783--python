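"""Example-based multi-label evaluation metrics.

Six standard metrics over r instances with q labels each: example-based
accuracy (mean Jaccard overlap of predicted and true label sets), average
precision, coverage, one-error, ranking loss, and Hamming loss, plus a
per-label accuracy table.  Ranks are descending (best score gets rank 1)
with deterministic ties broken toward the lower label index; the tie-break
matters for one-error and is documented because ranking loss counts tied
(true, false) score pairs as violations.

Instances whose true set is the full universe are excluded from ranking
loss (the complement set is empty, leaving the pair fraction undefined);
the number of skipped instances is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd


@dataclass
class EvaluationBatch:
    """Per-instance true sets, predicted sets and score vectors.

    ``true`` and ``predicted`` are r x q boolean matrices; ``scores`` is
    r x q real.  Every true set must be non-empty.
    """

    true: np.ndarray
    predicted: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.true = np.atleast_2d(np.asarray(self.true)).astype(bool)
        self.predicted = np.atleast_2d(np.asarray(self.predicted)).astype(bool)
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=np.float64))
        if not (self.true.shape == self.predicted.shape == self.scores.shape):
            raise ValueError("true/predicted/scores shapes disagree")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if (~self.true.any(axis=1)).any():
            raise ValueError("every instance needs a non-empty true label set")

    @property
    def r(self) -> int:
        return self.true.shape[0]

    @property
    def q(self) -> int:
        return self.true.shape[1]


@dataclass
class MetricsReport:
    acc_exam: float
    average_precision: float
    coverage: float
    one_error: float
    ranking_loss: float
    hamming_loss: float
    ranking_loss_skipped: int = 0
    per_label: pd.DataFrame | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "acc_exam": self.acc_exam,
            "average_precision": self.average_precision,
            "coverage": self.coverage,
            "one_error": self.one_error,
            "ranking_loss": self.ranking_loss,
            "hamming_loss": self.hamming_loss,
            "ranking_loss_skipped": self.ranking_loss_skipped,
        }
        if self.per_label is not None:
            out["per_label"] = json.loads(self.per_label.to_json())
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def rank_descending(scores: np.ndarray) -> np.ndarray:
    """Descending ranks 1..q per row; ties go to the lower label index."""
    scores = np.asarray(scores, dtype=np.float64)
    single = scores.ndim == 1
    scores = np.atleast_2d(scores)
    order = np.argsort(-scores, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(scores.shape[0])[:, None]
    ranks[rows, order] = np.arange(1, scores.shape[1] + 1)
    return ranks[0] if single else ranks


def acc_exam(batch: EvaluationBatch) -> float:
    """Mean Jaccard overlap |P∩T| / |P∪T| over instances."""
    inter = (batch.true & batch.predicted).sum(axis=1)
    union = (batch.true | batch.predicted).sum(axis=1)
    return float(np.mean(inter / union))

def average_precision(batch: EvaluationBatch) -> float:
    """For each instance, average over true labels t of the precision of the
    rank list cut at t's rank; higher is better, 1 means the true labels fill
    the top ranks."""
    ranks = rank_descending(batch.scores)
    vals = np.empty(batch.r)
    for i in range(batch.r):
        true_ranks = np.sort(ranks[i][batch.true[i]])
        vals[i] = np.mean(np.arange(1, len(true_ranks) + 1) / true_ranks)
    return float(vals.mean())


def coverage(batch: EvaluationBatch) -> float:
    """Mean (rank of the worst-ranked true label) - 1; range [0, q-1]."""
    ranks = rank_descending(batch.scores)
    worst = np.where(batch.true, ranks, 0).max(axis=1)
    return float(np.mean(worst - 1))


def one_error(batch: EvaluationBatch) -> float:
    """Fraction of instances whose rank-1 label is not a true label."""
    ranks = rank_descending(batch.scores)
    top = np.argmin(ranks, axis=1)
    return float(np.mean(~batch.true[np.arange(batch.r), top]))


def ranking_loss(batch: EvaluationBatch) -> tuple[float, int]:
    """Mean fraction of (true, false) pairs with score(true) <= score(false).

    Ties count as violations.  Returns (loss, number of skipped instances
    whose true set is the full universe).
    """
    vals = []
    skipped = 0
    for i in range(batch.r):
        t = batch.true[i]
        if t.all():
            skipped += 1
            continue
        s_true = batch.scores[i][t]
        s_false = batch.scores[i][~t]
        bad = (s_true[:, None] <= s_false[None, :]).sum()
        vals.append(bad / (len(s_true) * len(s_false)))
    if not vals:
        raise ValueError(
            "ranking loss undefined: every instance carries the full label set"
        )
    return float(np.mean(vals)), skipped


def hamming_loss(batch: EvaluationBatch) -> float:
    """Mean fraction of label slots where prediction and truth disagree."""
    return float(np.mean((batch.true ^ batch.predicted).sum(axis=1) / batch.q))


def per_label_metrics(
    batch: EvaluationBatch, labels: list[str] | None = None
) -> pd.DataFrame:
    """Per-label table with two 'accuracy' readings.

    ``recall``: among instances truly carrying the label, the fraction
    predicted to carry it (NaN if the label never occurs).  ``binary_accuracy``:
    the fraction of all instances where the label's predicted presence
    matches its true presence; its mean over labels equals 1 - Hamming loss.
    """
    positives = batch.true.sum(axis=0)
    hits = (batch.true & batch.predicted).sum(axis=0)
    with np.errstate(invalid="ignore"):
        recall = np.where(positives > 0, hits / np.maximum(positives, 1), np.nan)
    binary = (batch.true == batch.predicted).mean(axis=0)
    index = labels if labels is not None else [f"label_{j}" for j in range(batch.q)]
    return pd.DataFrame(
        {"recall": recall, "binary_accuracy": binary, "positives": positives},
        index=index,
    )


def evaluate_all(
    batch: EvaluationBatch, labels: list[str] | None = None
) -> MetricsReport:
    """All six metrics plus the per-label table in one report."""
    rl, skipped = ranking_loss(batch)
    return MetricsReport(
        acc_exam=acc_exam(batch),
        average_precision=average_precision(batch),
        coverage=coverage(batch),
        one_error=one_error(batch),
        ranking_loss=rl,
        hamming_loss=hamming_loss(batch),
        ranking_loss_skipped=skipped,
        per_label=per_label_metrics(batch, labels),
    )
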