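"""Label co-occurrence model and per-instance prior vectors.

All nine compartment labels are fully observed binary variables, so the
quantities the downstream classifier consumes — marginal probabilities,
pairwise joint/conditional co-occurrence probabilities, and the per-record
"retained probabilities + shared mean" prior vector — are exact empirical
tables (with optional additive smoothing).  An optional Chow-Liu tree
exposes an explicit dependency structure for users who want one.

At prediction time a test record has no labels, so its prior is borrowed
from the most similar training record (cosine similarity between pooled
sequence embeddings, exhaustive scan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset import CompartmentUniverse


@dataclass
class CooccurrenceModel:
    """Empirical marginal / joint / conditional probability tables.

    ``marginal[i] = P(X_i=1)``; ``joint[i, j] = P(X_i=1, X_j=1)``;
    ``conditional[i, j] = P(X_j=1 | X_i=1)`` (NaN where the conditioning
    marginal is zero and no smoothing is applied).  An implied co-occurrence
    edge (i, j) exists wherever ``joint[i, j] > 0``.
    """

    universe: CompartmentUniverse
    marginal: np.ndarray
    joint: np.ndarray
    conditional: np.ndarray = field(repr=False)
    alpha: float = 0.0

    @property
    def q(self) -> int:
        return self.universe.q

    def conditional_row(self, i: int) -> np.ndarray:
        row = self.conditional[i]
        if np.isnan(row).any():
            raise ValueError(
                f"conditional probabilities given {self.universe.labels[i]!r} are "
                "undefined (marginal is zero; use smoothing alpha > 0)"
            )
        return row

    def edges(self) -> list[tuple[int, int]]:
        """Pairs (i < j) whose labels co-occur at least once."""
        q = self.q
        return [(i, j) for i in range(q) for j in range(i + 1, q) if self.joint[i, j] > 0]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "labels": list(self.universe.labels),
                    "alpha": self.alpha,
                    "marginal": self.marginal.tolist(),
                    "joint": self.joint.tolist(),
                    "conditional": self.conditional.tolist(),
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "CooccurrenceModel":
        data = json.loads(Path(path).read_text())
        return cls(
            universe=CompartmentUniverse(tuple(data["labels"])),
            marginal=np.array(data["marginal"]),
            joint=np.array(data["joint"]),
            conditional=np.array(data["conditional"]),
            alpha=data["alpha"],
        )


@dataclass
class PriorVector:
    """Length-q prior: retained probabilities for the record's own labels,
    one shared mean for every other label."""

    values: np.ndarray
    in_set: frozenset[str]


def fit_cooccurrence(
    label_matrix: np.ndarray,
    alpha: float = 0.0,
    universe: CompartmentUniverse | None = None,
    normalization: str = "records",
) -> CooccurrenceModel:
    """Estimate the co-occurrence model from an r x q binary label matrix.

    With pseudo-count ``alpha``, ``marginal[i] = (n_i + alpha) / (r + 2*alpha)``
    and ``joint[i, j] = (n_ij + alpha) / (r + 2*alpha)``.
    ``normalization="assignments"`` divides counts by the total number of
    label assignments instead of the number of records; conditionals are the
    same count ratios either way.
    """
    X = np.asarray(label_matrix, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("label matrix must be r x q with r >= 1")
    r, q = X.shape
    universe = universe or CompartmentUniverse()
    if universe.q != q:
        raise ValueError("universe size does not match label matrix width")
    if normalization not in ("records", "assignments"):
        raise ValueError("normalization must be 'records' or 'assignments'")

    counts = X.sum(axis=0)
    pair_counts = X.T @ X
    denom = (r if normalization == "records" else X.sum()) + 2.0 * alpha
    marginal = (counts + alpha) / denom
    joint = (pair_counts + alpha) / denom
    with np.errstate(divide="ignore", invalid="ignore"):
        conditional = np.where(
            (counts + alpha)[:, None] > 0,
            (pair_counts + alpha) / (counts + alpha)[:, None],
            np.nan,
        )
    return CooccurrenceModel(
        universe=universe,
        marginal=marginal,
        joint=joint,
        conditional=conditional,
        alpha=alpha,
    )


def prior_for_labelset(
    model: CooccurrenceModel,
    labels: frozenset[str] | set[str],
    retained: str = "marginal",
) -> PriorVector:
    """Build the per-record prior vector from a known label set.

    Coordinates of the record's own labels retain their model probability;
    every other coordinate carries the mean of the remaining labels'
    probabilities.  ``retained="marginal"`` uses marginal probabilities (the
    per-label scalars the model tabulates); ``retained="conditional"`` uses,
    for each label, the mean conditional probability given the other in-set
    labels (falling back to the marginal for singleton sets).
    """
    if not labels:
        raise ValueError("empty label set")
    labels = frozenset(labels)
    idx = np.array(sorted(model.universe.index(l) for l in labels))
    base = model.marginal.copy()
    if retained == "conditional" and len(idx) > 1:
        for i in idx:
            others = idx[idx != i]
            base[i] = model.conditional[others, i].mean()
    elif retained not in ("marginal", "conditional"):
        raise ValueError("retained must be 'marginal' or 'conditional'")

    values = np.empty(model.q, dtype=np.float64)
    in_mask = np.zeros(model.q, dtype=bool)
    in_mask[idx] = True
    values[in_mask] = base[in_mask]
    if (~in_mask).any():
        values[~in_mask] = base[~in_mask].mean()
    return PriorVector(values=values, in_set=labels)


def transfer_prior_nn(
    test_vec: np.ndarray,
    train_vecs: np.ndarray,
    train_priors: list[PriorVector],
) -> PriorVector:
    """Borrow the prior of the most cosine-similar training record.

    Ties are broken toward the lowest training index; a zero-norm query is
    rejected (no direction to compare).
    """
    return train_priors[nearest_neighbor_index(test_vec, train_vecs)]


def nearest_neighbor_index(test_vec: np.ndarray, train_vecs: np.ndarray) -> int:
    test_vec = np.asarray(test_vec, dtype=np.float64)
    train_vecs = np.asarray(train_vecs, dtype=np.float64)
    if train_vecs.ndim != 2 or len(train_vecs) == 0:
        raise ValueError("need at least one training vector")
    if train_vecs.shape[1] != test_vec.shape[0]:
        raise ValueError("dimension mismatch between query and training vectors")
    qn = np.linalg.norm(test_vec)
    if qn == 0:
        raise ValueError("zero-norm query vector has no cosine similarity")
    norms = np.linalg.norm(train_vecs, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = (train_vecs @ test_vec) / (norms * qn)
    sims = np.where(norms == 0, -np.inf, sims)
    return int(np.argmax(sims))  # argmax returns the first (lowest) index on ties


def chow_liu_tree(model: CooccurrenceModel) -> list[tuple[int, int]]:
    """Maximum-mutual-information spanning tree over the label variables.

    Returns undirected edges (i < j).  This gives users an explicit sparse
    dependency structure; the classifier itself consumes the dense tables.
    """
    import networkx as nx

    q = model.q
    g = nx.Graph()
    g.add_nodes_from(range(q))
    m = model.marginal
    for i in range(q):
        for j in range(i + 1, q):
            mi = 0.0
            for a in (0, 1):
                for b in (0, 1):
                    pa = m[i] if a else 1 - m[i]
                    pb = m[j] if b else 1 - m[j]
                    if a and b:
                        pab = model.joint[i, j]
                    elif a:
                        pab = m[i] - model.joint[i, j]
                    elif b:
                        pab = m[j] - model.joint[i, j]
                    else:
                        pab = 1 - m[i] - m[j] + model.joint[i, j]
                    if pab > 0 and pa > 0 and pb > 0:
                        mi += pab * np.log(pab / (pa * pb))
            g.add_edge(i, j, weight=mi)
    tree = nx.maximum_spanning_tree(g, weight="weight")
    return sorted(tuple(sorted(e)) for e in tree.edges)
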