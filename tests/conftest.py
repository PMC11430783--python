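import numpy as np
import pytest

from rnaloc.dataset import CompartmentUniverse, LabeledSequence, LocalizationDataset
from rnaloc.metrics import EvaluationBatch


@pytest.fixture
def universe9() -> CompartmentUniverse:
    return CompartmentUniverse()


@pytest.fixture
def worked_batch() -> EvaluationBatch:
    """Two q=3 instances computable by hand.

    Instance 0: T={L0,L2}, P={L1,L2}, scores (0.2, 0.9, 0.6) — ranks are
    L1=1, L2=2, L0=3.  Instance 1 is predicted and ranked perfectly with
    T=P={L0,L1}.
    """
    true = np.array([[1, 0, 1], [1, 1, 0]], dtype=bool)
    pred = np.array([[0, 1, 1], [1, 1, 0]], dtype=bool)
    scores = np.array([[0.2, 0.9, 0.6], [0.9, 0.8, 0.1]])
    return EvaluationBatch(true, pred, scores)


def random_batch(rng: np.random.Generator, r: int, q: int) -> EvaluationBatch:
    """Random evaluation batch with non-empty true sets and tie-prone scores."""
    true = rng.random((r, q)) < rng.uniform(0.2, 0.7)
    for i in np.flatnonzero(~true.any(axis=1)):
        true[i, rng.integers(q)] = True
    pred = rng.random((r, q)) < 0.5
    # quantized scores make ties common, exercising the tie-break rules
    scores = np.round(rng.random((r, q)), 1)
    return EvaluationBatch(true, pred, scores)


@pytest.fixture
def tiny_dataset(universe9) -> LocalizationDataset:
    records = [
        LabeledSequence("r1", "ATGGCATGC", frozenset({"exosome"})),
        LabeledSequence("r2", "CCGTACGTA", frozenset({"exosome", "nucleus"})),
        LabeledSequence("r3", "TTTTACGCA", frozenset({"ribosome"})),
    ]
    return LocalizationDataset(universe9, records)
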