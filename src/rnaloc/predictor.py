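"""Training and inference for the prior-fused BiLSTM+attention classifier.

Each sequence is tokenized into k-mers, embedded row-by-row from the
skip-gram table, and — when prior fusion is on — its length-q prior vector
is broadcast-concatenated to every time step, so the recurrent layers and
attention can condition on the label co-occurrence prior throughout the
sequence.  Training records use the prior built from their own true label
set; test records borrow the prior of their nearest training neighbour in
pooled-embedding space (never their own labels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .dataset import LocalizationDataset
from .encoding import EmbeddingTable, TokenizerConfig, embed_tokens, pool_sequence_vector, segment
from .nn import Adam, BiLSTMAttention
from .prior import CooccurrenceModel, PriorVector, nearest_neighbor_index, prior_for_labelset


@dataclass
class ModelConfig:
    """Classifier hyperparameters (per-direction hidden size, ablation flags,
    optimization settings, decision threshold)."""

    hidden: int = 24
    bidirectional: bool = True
    attention: bool = True
    dropout: float = 0.1
    max_len: int = 4000
    batch: int = 64
    lr: float = 1e-3
    epochs: int = 10
    threshold: float = 0.5
    seed: int = 0
    prior_fusion: str = "broadcast"  # "none" drops the channel; "zero"
    # keeps the channel and architecture but feeds an all-zero prior — the
    # matched ablation control (same init, same trajectory noise)
    train_prior: str = "transfer"  # or "true_labels"
    prior_to_output: bool = False
    prior_neighbors: int = 1
    standardize_features: bool = True
    standardize_prior: bool = False

    def __post_init__(self) -> None:
        if self.hidden < 1:
            raise ValueError("hidden must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.prior_fusion not in ("broadcast", "none", "zero"):
            raise ValueError("prior_fusion must be 'broadcast', 'none' or 'zero'")
        if self.train_prior not in ("transfer", "true_labels"):
            raise ValueError("train_prior must be 'transfer' or 'true_labels'")
        if self.prior_neighbors < 1:
            raise ValueError("prior_neighbors must be >= 1")


def fuse_prior(token_matrix: np.ndarray, prior: PriorVector | np.ndarray) -> np.ndarray:
    """Append the length-q prior to every token row (broadcast concatenation)."""
    values = prior.values if isinstance(prior, PriorVector) else np.asarray(prior)
    token_matrix = np.asarray(token_matrix)
    if token_matrix.ndim != 2:
        raise ValueError("token matrix must be 2-D")
    tiled = np.broadcast_to(values, (token_matrix.shape[0], values.shape[0]))
    return np.concatenate([token_matrix, tiled], axis=1)


def decide_labels(scores: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean decisions: score >= threshold, with a top-1 fallback so every
    record gets at least one label (every mRNA has >= 1 localization)."""
    scores = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    decided = scores >= threshold
    empty = ~decided.any(axis=1)
    if empty.any():
        top = scores[empty].argmax(axis=1)
        decided[np.flatnonzero(empty), top] = True
    return decided


def _features(
    ds: LocalizationDataset,
    table: EmbeddingTable,
    priors: list[PriorVector] | None,
    max_len: int,
) -> tuple[list[np.ndarray], np.ndarray, list[list[str]]]:
    feats, lengths, token_lists = [], [], []
    for i, rec in enumerate(ds.records):
        tokens = segment(rec.sequence, TokenizerConfig(k=table.k))[:max_len]
        mat = embed_tokens(tokens, table).astype(np.float32)
        if priors is not None:
            mat = fuse_prior(mat, priors[i]).astype(np.float32)
        feats.append(mat)
        lengths.append(len(tokens))
        token_lists.append(tokens)
    return feats, np.array(lengths, dtype=np.int64), token_lists


def _consensus_label_set(
    sims: np.ndarray, label_matrix: np.ndarray, universe, k: int
) -> frozenset[str]:
    """Majority-vote label set of the k most similar training records.

    Falls back to the single nearest record's set if no label reaches a
    majority (every record must imply a non-empty set).
    """
    top = np.argsort(-sims, kind="stable")[:k]
    votes = label_matrix[top].mean(axis=0)
    consensus = votes > 0.5
    if not consensus.any():
        consensus = label_matrix[top[0]].astype(bool)
    return frozenset(universe.labels[j] for j in np.flatnonzero(consensus))


def _cosine_sims(query: np.ndarray, unit_rows: np.ndarray) -> np.ndarray:
    qn = np.linalg.norm(query)
    if qn == 0:
        raise ValueError("zero-norm query vector has no cosine similarity")
    return unit_rows @ (query / qn)


def _unit_rows(vectors: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(vectors, axis=1, keepdims=True)
    return np.where(norms > 0, vectors / np.maximum(norms, 1e-300), 0.0)


def _length_batches(lengths: np.ndarray, batch: int) -> list[np.ndarray]:
    """Batches of similar length (stable sort) to limit padding waste."""
    order = np.argsort(lengths, kind="stable")
    return [order[i : i + batch] for i in range(0, len(order), batch)]


def _pad(feats: list[np.ndarray], idx: np.ndarray, lengths: np.ndarray):
    T = int(lengths[idx].max())
    D = feats[idx[0]].shape[1]
    X = np.zeros((len(idx), T, D), dtype=np.float32)
    for row, i in enumerate(idx):
        X[row, : lengths[i]] = feats[i]
    return X, lengths[idx]


class TrainedPredictor:
    """Trained network plus every artifact inference needs: the embedding
    table, the co-occurrence model, and the training pooled vectors +
    priors for nearest-neighbour prior transfer."""

    def __init__(
        self,
        net: BiLSTMAttention,
        config: ModelConfig,
        table: EmbeddingTable,
        coocc: CooccurrenceModel,
        train_pooled: np.ndarray,
        train_priors: list[PriorVector],
        loss_history: list[float],
        prior_mu: np.ndarray | None = None,
        prior_sd: np.ndarray | None = None,
    ):
        self.net = net
        self.config = config
        self.table = table
        self.coocc = coocc
        self.train_pooled = train_pooled
        self.train_priors = train_priors
        self.loss_history = loss_history
        q = coocc.universe.q
        self.prior_mu = prior_mu if prior_mu is not None else np.zeros(q)
        self.prior_sd = prior_sd if prior_sd is not None else np.ones(q)

    @property
    def universe(self):
        return self.coocc.universe

    def predict_scores(self, ds: LocalizationDataset) -> np.ndarray:
        """Per-label sigmoid scores (r, q); priors come from NN transfer."""
        use_channel = self.config.prior_fusion in ("broadcast", "zero")
        use_prior = self.config.prior_fusion == "broadcast"
        priors = None
        if use_prior:
            universe = self.universe
            train_labels = np.array(
                [
                    [label in p.in_set for label in universe.labels]
                    for p in self.train_priors
                ],
                dtype=np.int8,
            )
            unit = _unit_rows(self.train_pooled)
            priors = []
            for rec in ds.records:
                tokens = segment(rec.sequence, TokenizerConfig(k=self.table.k))
                pooled = pool_sequence_vector(tokens, self.table)
                if self.config.prior_neighbors == 1:
                    raw = self.train_priors[nearest_neighbor_index(pooled, self.train_pooled)]
                else:
                    labels = _consensus_label_set(
                        _cosine_sims(pooled, unit), train_labels, universe,
                        self.config.prior_neighbors,
                    )
                    raw = prior_for_labelset(self.coocc, labels)
                priors.append(
                    PriorVector(
                        values=(raw.values - self.prior_mu) / self.prior_sd,
                        in_set=raw.in_set,
                    )
                )
        elif use_channel:
            q = self.net.q
            priors = [
                PriorVector(values=np.zeros(q), in_set=frozenset()) for _ in ds.records
            ]
        feats, lengths, _ = _features(ds, self.table, priors, self.config.max_len)
        prior_matrix = (
            np.array([p.values for p in priors], dtype=np.float32)
            if (use_channel and self.net.extra_dim) else None
        )
        scores = np.empty((len(ds), self.net.q), dtype=np.float64)
        for idx in _length_batches(lengths, self.config.batch):
            X, lens = _pad(feats, idx, lengths)
            extra = prior_matrix[idx] if prior_matrix is not None else None
            scores[idx] = self.net.predict_scores(X, lens, extra=extra)
        return scores

    def predict_labels(self, ds: LocalizationDataset) -> np.ndarray:
        return decide_labels(self.predict_scores(ds), self.config.threshold)

    # ------------------------------------------------------------ persistence

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.net.save(directory / "net")
        self.table.save(directory / "embedding")
        self.coocc.to_json(directory / "cooccurrence.json")
        (directory / "config.json").write_text(json.dumps(asdict(self.config)))
        np.savetxt(directory / "train_pooled.tsv", self.train_pooled, delimiter="\t")
        with open(directory / "train_priors.tsv", "w") as fh:
            for p in self.train_priors:
                labels = ",".join(sorted(p.in_set))
                fh.write(labels + "\t" + "\t".join(f"{v:.17g}" for v in p.values) + "\n")
        (directory / "loss_history.json").write_text(json.dumps(self.loss_history))
        np.savetxt(
            directory / "prior_scale.tsv",
            np.vstack([self.prior_mu, self.prior_sd]),
            delimiter="\t",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedPredictor":
        directory = Path(directory)
        net = BiLSTMAttention.load(directory / "net")
        table = EmbeddingTable.load(directory / "embedding")
        coocc = CooccurrenceModel.from_json(directory / "cooccurrence.json")
        config = ModelConfig(**json.loads((directory / "config.json").read_text()))
        pooled = np.loadtxt(directory / "train_pooled.tsv", delimiter="\t", ndmin=2)
        priors = []
        for line in (directory / "train_priors.tsv").read_text().splitlines():
            parts = line.split("\t")
            priors.append(
                PriorVector(
                    values=np.array([float(x) for x in parts[1:]]),
                    in_set=frozenset(parts[0].split(",")),
                )
            )
        history = json.loads((directory / "loss_history.json").read_text())
        scale = np.loadtxt(directory / "prior_scale.tsv", delimiter="\t", ndmin=2)
        return cls(
            net, config, table, coocc, pooled, priors, history,
            prior_mu=scale[0], prior_sd=scale[1],
        )


def train(
    train_ds: LocalizationDataset,
    table: EmbeddingTable,
    coocc: CooccurrenceModel,
    cfg: ModelConfig,
) -> TrainedPredictor:
    """Fit the (Bi)LSTM+attention classifier on a labeled training set.

    Optimizes mean per-label binary cross-entropy with Adam.  With
    ``train_prior="transfer"`` (default) each training instance is fused
    with the prior of its leave-one-out nearest neighbour, matching the
    noise the prior channel carries at prediction time;
    ``train_prior="true_labels"`` fuses the prior built from the instance's
    own label set instead.  The loss trajectory is recorded per epoch and
    is deterministic for a fixed seed.
    """
    if len(train_ds) == 0:
        raise ValueError("empty training set")
    if coocc.universe.q != train_ds.universe.q:
        raise ValueError("co-occurrence model does not match the dataset universe")

    if cfg.standardize_features:
        table = table.standardized()
    use_channel = cfg.prior_fusion in ("broadcast", "zero")
    use_prior = cfg.prior_fusion == "broadcast"
    priors = [prior_for_labelset(coocc, rec.label_set) for rec in train_ds.records]

    # pooled (unfused, untruncated) sequence vectors; reused for test-time
    # NN prior transfer and, in "transfer" mode, for training priors
    pooled = np.array(
        [
            pool_sequence_vector(segment(rec.sequence, TokenizerConfig(k=table.k)), table)
            for rec in train_ds.records
        ]
    )

    if cfg.train_prior == "transfer" and use_prior and len(train_ds) > 1:
        # leave-one-out neighbour transfer: each training record is fused
        # with the prior its own prediction-time transfer would produce
        # (consensus of the most similar *other* records), so the prior
        # channel has the same noise distribution at training and
        # prediction time
        unit = _unit_rows(pooled)
        sims = unit @ unit.T
        np.fill_diagonal(sims, -np.inf)
        if cfg.prior_neighbors == 1:
            fit_priors = [priors[j] for j in sims.argmax(axis=1)]
        else:
            fit_priors = [
                prior_for_labelset(
                    coocc,
                    _consensus_label_set(
                        sims[i], train_ds.label_matrix, train_ds.universe,
                        cfg.prior_neighbors,
                    ),
                )
                for i in range(len(train_ds))
            ]
    else:
        fit_priors = priors
    q = train_ds.universe.q
    if cfg.prior_fusion == "zero":
        fit_priors = [
            PriorVector(values=np.zeros(q), in_set=frozenset()) for _ in priors
        ]

    # optionally bring the prior channel onto the embedding feature scale;
    # off by default — amplifying a noisy transferred prior amplifies its
    # distraction as much as its information
    prior_mu = np.zeros(q)
    prior_sd = np.ones(q)
    if use_prior and cfg.standardize_prior:
        P = np.array([p.values for p in fit_priors])
        prior_mu = P.mean(axis=0)
        prior_sd = P.std(axis=0) + 1e-8
        fit_priors = [
            PriorVector(values=(p.values - prior_mu) / prior_sd, in_set=p.in_set)
            for p in fit_priors
        ]

    feats, lengths, token_lists = _features(
        train_ds, table, fit_priors if use_channel else None, cfg.max_len
    )
    input_dim = table.dim + (q if use_channel else 0)
    extra_dim = q if (use_channel and cfg.prior_to_output) else 0
    prior_matrix = np.array([p.values for p in fit_priors], dtype=np.float32)
    net = BiLSTMAttention(
        input_dim=input_dim,
        hidden=cfg.hidden,
        q=q,
        bidirectional=cfg.bidirectional,
        attention=cfg.attention,
        dropout=cfg.dropout,
        extra_dim=extra_dim,
        seed=cfg.seed,
    )
    optimizer = Adam(net.params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    Y = train_ds.label_matrix.astype(np.float32)

    batches = _length_batches(lengths, cfg.batch)
    history: list[float] = []
    for _ in range(cfg.epochs):
        order = rng.permutation(len(batches))
        total, count = 0.0, 0
        for bi in order:
            idx = batches[bi]
            X, lens = _pad(feats, idx, lengths)
            extra = prior_matrix[idx] if extra_dim else None
            loss, grads, _ = net.loss_and_grads(
                X, lens, Y[idx], extra=extra,
                dropout_rng=rng if cfg.dropout > 0 else None,
            )
            optimizer.step(net.params, grads)
            total += float(loss) * len(idx)
            count += len(idx)
        history.append(total / count)

    return TrainedPredictor(
        net, cfg, table, coocc, pooled, priors, history,
        prior_mu=prior_mu, prior_sd=prior_sd,
    )
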