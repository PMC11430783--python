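"""Reusable study-scale evaluation runs shared by the acceptance script.

Collects, in one place, the desk-scale experiment the package uses to
demonstrate end-to-end learnability and the two ablation orderings
(prior fusion vs none; BiLSTM+attention vs plain LSTM) on the synthetic
benchmark conditions: 1,000 sequences, planted motifs with Poisson mean 3
copies, lengths 200-400 nt, a 9:1 split, and at most 20 training epochs.
"""

from __future__ import annotations

import numpy as np

from . import simulate as sim
from .dataset import SplitSpec, split_train_test
from .encoding import SkipgramConfig, segment, train_skipgram
from .metrics import EvaluationBatch, acc_exam
from .predictor import ModelConfig, decide_labels, train
from .prior import fit_cooccurrence

#: Study conditions for the learnability experiment.
N_SEQUENCES = 1000
MOTIF_COPIES = 3.0
LENGTH_RANGE = (200, 400)
TEST_FRACTION = 0.1
MAX_EPOCHS = 20

#: Package defaults for the desk-scale model (documented in the methods note).
SKIPGRAM = dict(dim=16, context=3, epochs=2)
MODEL = dict(hidden=32, epochs=MAX_EPOCHS, lr=1e-2, batch=64, dropout=0.1)

ARMS = {
    "prior": {},
    "no_prior": {"prior_fusion": "none"},
    "lstm": {"bidirectional": False, "attention": False},
}


def run_arms(seed: int, arms: list[str] | None = None) -> dict[str, float]:
    """Simulate one dataset, then train/evaluate the requested model arms.

    All arms share the dataset, split, embedding table and co-occurrence
    model, so comparisons differ only in the classifier configuration.
    Returns held-out example-based accuracy per arm.
    """
    arms = arms or list(ARMS)
    cfg = sim.SyntheticConfig(
        joint=sim.chain_joint(),
        motifs=sim.default_motifs(copies=MOTIF_COPIES),
        n=N_SEQUENCES,
        length_range=LENGTH_RANGE,
        seed=seed,
    )
    ds = sim.simulate_dataset(cfg)
    train_ds, test_ds = split_train_test(ds, SplitSpec(TEST_FRACTION, seed))
    corpus = [segment(rec.sequence) for rec in ds.records]
    table = train_skipgram(corpus, SkipgramConfig(seed=seed, **SKIPGRAM))
    coocc = fit_cooccurrence(train_ds.label_matrix, universe=ds.universe)

    out: dict[str, float] = {}
    for arm in arms:
        mcfg = ModelConfig(seed=seed, **MODEL, **ARMS[arm])
        predictor = train(train_ds, table, coocc, mcfg)
        scores = predictor.predict_scores(test_ds)
        batch = EvaluationBatch(
            test_ds.label_matrix.astype(bool), decide_labels(scores), scores
        )
        out[arm] = acc_exam(batch)
    return out


def replicate_seeds(seed: int, n: int = 3) -> list[int]:
    """n replicate seeds derived deterministically from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s % (2**31)) for s in state]
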