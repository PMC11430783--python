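"""k-mer tokenization and skip-gram embeddings for nucleotide sequences.

A sequence of length L is cut into its L-k+1 overlapping k-mers (window
size k, stride 1); each k-mer is treated as a word and each sequence as a
sentence, and a skip-gram model learns a dense vector per k-mer from the
co-occurrence of k-mers within a context window.  A classical k-mer
frequency encoder is included as the baseline representation.

The skip-gram trainer is a native vectorized implementation (minibatch SGD
with negative sampling, or the exact softmax objective for small
vocabularies such as the 64 DNA 3-mers).  Training is deterministic for a
fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np

#: Reserved token for k-mers containing ambiguous bases (N) and for
#: out-of-vocabulary lookups.  Its embedding row is pinned at zero and is
#: excluded from skip-gram training.
UNK = "<unk>"

_BASES = "ACGT"


@dataclass(frozen=True)
class TokenizerConfig:
    """Sliding-window tokenizer: window size ``k`` nucleotides, stride 1."""

    k: int = 3
    step: int = 1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.step != 1:
            raise ValueError("stride is fixed at 1")


def segment(sequence: str, cfg: TokenizerConfig | None = None) -> list[str]:
    """Overlapping k-mers of ``sequence``, in order; exactly L-k+1 tokens.

    Windows containing an ambiguous base become the :data:`UNK` token.
    """
    cfg = cfg or TokenizerConfig()
    k = cfg.k
    if len(sequence) < k:
        raise ValueError(
            f"sequence shorter than window: length {len(sequence)} < k={k}"
        )
    tokens = []
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        tokens.append(UNK if "N" in kmer else kmer)
    return tokens


@dataclass(frozen=True)
class SkipgramConfig:
    """Hyperparameters of the skip-gram embedder.

    ``context`` is the maximum distance between the central k-mer and a
    predicted context k-mer.  ``negative`` > 0 selects the negative-sampling
    surrogate objective; ``negative = 0`` trains the exact softmax over the
    whole vocabulary (feasible for small k; the DNA 3-mer vocabulary has
    only 64 entries).
    """

    dim: int = 100
    context: int = 5
    epochs: int = 10
    negative: int = 5
    min_count: int = 1
    lr: float = 0.5
    min_lr: float = 0.01
    batch: int = 4096
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.context < 1:
            raise ValueError("context must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class EmbeddingTable:
    """k-mer -> vector lookup with a reserved UNK row (always row 0)."""

    def __init__(self, tokens: Sequence[str], vectors: np.ndarray, k: int):
        if tokens[0] != UNK:
            raise ValueError("row 0 must be the UNK token")
        if len(tokens) != vectors.shape[0]:
            raise ValueError("token list and vector matrix disagree")
        self.tokens = list(tokens)
        self.vectors = np.asarray(vectors, dtype=np.float64)
        self.k = k
        self._index = {tok: i for i, tok in enumerate(self.tokens)}

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def vocabulary(self) -> list[str]:
        """Trained tokens, UNK excluded."""
        return self.tokens[1:]

    def row(self, token: str) -> int:
        return self._index.get(token, 0)

    def vector(self, token: str) -> np.ndarray:
        return self.vectors[self.row(token)]

    def standardized(self, eps: float = 1e-8) -> "EmbeddingTable":
        """Per-dimension zero-mean / unit-variance copy (UNK row kept at zero).

        Trained skip-gram vectors share a large common component (all tokens
        are attracted to their contexts), which hides the between-token
        differences that carry the signal; centering and scaling across the
        vocabulary removes it.
        """
        vocab_rows = self.vectors[1:]
        mu = vocab_rows.mean(axis=0)
        sd = vocab_rows.std(axis=0) + eps
        out = (self.vectors - mu) / sd
        out[0] = 0.0
        return EmbeddingTable(self.tokens, out, k=self.k)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "tokens.txt").write_text("\n".join(self.tokens) + "\n")
        np.savetxt(directory / "vectors.tsv", self.vectors, delimiter="\t")
        (directory / "meta.json").write_text(
            json.dumps({"k": self.k, "dim": self.dim})
        )

    @classmethod
    def load(cls, directory: str | Path) -> "EmbeddingTable":
        directory = Path(directory)
        tokens = (directory / "tokens.txt").read_text().splitlines()
        vectors = np.loadtxt(directory / "vectors.tsv", delimiter="\t", ndmin=2)
        meta = json.loads((directory / "meta.json").read_text())
        return cls(tokens, vectors, k=meta["k"])


def _build_vocab(corpus: Sequence[Sequence[str]], min_count: int):
    counts: dict[str, int] = {}
    for sentence in corpus:
        for tok in sentence:
            if tok != UNK:
                counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        (tok for tok, c in counts.items() if c >= min_count),
        key=lambda tok: (-counts[tok], tok),
    )
    freqs = np.array([counts[tok] for tok in kept], dtype=np.float64)
    return kept, freqs


def _training_pairs(
    corpus: Sequence[Sequence[str]], index: dict[str, int], context: int
) -> tuple[np.ndarray, np.ndarray]:
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for sentence in corpus:
        ids = np.array([index.get(tok, -1) for tok in sentence], dtype=np.int64)
        n = len(ids)
        for d in range(1, context + 1):
            if n <= d:
                break
            left, right = ids[:-d], ids[d:]
            ok = (left >= 0) & (right >= 0)
            if ok.any():
                centers.append(left[ok])
                contexts.append(right[ok])
                centers.append(right[ok])
                contexts.append(left[ok])
    if not centers:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    return np.concatenate(centers), np.concatenate(contexts)


def train_skipgram(
    corpus: Sequence[Sequence[str]], cfg: SkipgramConfig, k: int | None = None
) -> EmbeddingTable:
    """Learn a k-mer embedding table from a tokenized corpus.

    Maximizes the average log probability of context k-mers within
    ``cfg.context`` positions of each central k-mer, via negative sampling
    (``cfg.negative`` > 0) or the exact softmax (``cfg.negative`` = 0).
    UNK tokens never participate; the UNK row stays at zero.
    """
    if not corpus:
        raise ValueError("empty corpus")
    if k is None:
        k = len(next(tok for s in corpus for tok in s if tok != UNK))
    for sentence in corpus:
        for tok in sentence:
            if tok != UNK and len(tok) != k:
                raise ValueError("corpus mixes window sizes")

    vocab, freqs = _build_vocab(corpus, cfg.min_count)
    if not vocab:
        raise ValueError("no token reaches min_count")
    index = {tok: i for i, tok in enumerate(vocab)}
    W = len(vocab)
    rng = np.random.default_rng(cfg.seed)

    vin = ((rng.random((W, cfg.dim)) - 0.5) / cfg.dim).astype(np.float64)
    vout = np.zeros((W, cfg.dim), dtype=np.float64)

    centers, contexts = _training_pairs(corpus, index, cfg.context)
    n_pairs = len(centers)
    if n_pairs == 0:
        # single-token sentences only: nothing to fit beyond the init
        return _finish_table(vocab, vin, cfg.dim, k)

    noise = freqs**0.75
    noise /= noise.sum()
    total_batches = cfg.epochs * max(1, int(np.ceil(n_pairs / cfg.batch)))
    batch_no = 0
    for _ in range(cfg.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, cfg.batch):
            sel = order[start : start + cfg.batch]
            lr = cfg.lr + (cfg.min_lr - cfg.lr) * (batch_no / total_batches)
            batch_no += 1
            ci, oi = centers[sel], contexts[sel]
            if cfg.negative > 0:
                _sgd_negative(vin, vout, ci, oi, noise, cfg.negative, lr, rng)
            else:
                _sgd_softmax(vin, vout, ci, oi, lr)
    return _finish_table(vocab, vin, cfg.dim, k)


def _finish_table(vocab, vin, dim, k) -> EmbeddingTable:
    vectors = np.vstack([np.zeros((1, dim)), vin])
    return EmbeddingTable([UNK] + list(vocab), vectors, k=k)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _sgd_negative(vin, vout, ci, oi, noise, n_neg, lr, rng) -> None:
    # minibatch gradient: mean over the pairs in the batch
    B, dim = len(ci), vin.shape[1]
    ni = rng.choice(len(noise), size=(B, n_neg), p=noise)
    vc = vin[ci]
    uo = vout[oi]
    un = vout[ni]
    g_pos = _sigmoid(np.einsum("bd,bd->b", vc, uo)) - 1.0
    g_neg = _sigmoid(np.einsum("bkd,bd->bk", un, vc))
    step = lr / B
    d_vc = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
    np.add.at(vin, ci, -step * d_vc)
    np.add.at(vout, oi, -step * g_pos[:, None] * vc)
    np.add.at(
        vout,
        ni.ravel(),
        (-step * g_neg[:, :, None] * vc[:, None, :]).reshape(-1, dim),
    )


def _sgd_softmax(vin, vout, ci, oi, lr) -> None:
    vc = vin[ci]
    B = len(ci)
    logits = vc @ vout.T
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    p[np.arange(B), oi] -= 1.0
    step = lr / B
    d_vc = p @ vout
    d_vout = p.T @ vc
    np.add.at(vin, ci, -step * d_vc)
    vout -= step * d_vout


def embed_tokens(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Row t is the embedding of token t; OOV/UNK tokens get the UNK row."""
    rows = np.fromiter((table.row(tok) for tok in tokens), dtype=np.int64, count=len(tokens))
    return table.vectors[rows]


def pool_sequence_vector(tokens: Sequence[str], table: EmbeddingTable) -> np.ndarray:
    """Fixed-length sequence vector: unweighted mean of token embeddings."""
    if not tokens:
        raise ValueError("cannot pool an empty token list")
    return embed_tokens(tokens, table).mean(axis=0)


def kmer_index(kmer: str) -> int:
    """Lexicographic index of a k-mer over the A<C<G<T alphabet."""
    idx = 0
    for base in kmer:
        idx = idx * 4 + _BASES.index(base)
    return idx


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in product(_BASES, repeat=k)]


def kmer_frequency_features(tokens: Sequence[str], k: int) -> np.ndarray:
    """Normalized k-mer count vector of length 4^k (the baseline encoder).

    UNK tokens are excluded from both numerator and denominator; the result
    is a probability vector.
    """
    counts = np.zeros(4**k, dtype=np.float64)
    for tok in tokens:
        if tok == UNK:
            continue
        if len(tok) != k:
            raise ValueError(f"token {tok!r} does not match k={k}")
        counts[kmer_index(tok)] += 1.0
    total = counts.sum()
    if total == 0:
        raise ValueError("all tokens are UNK; no k-mer frequencies defined")
    return counts / total
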