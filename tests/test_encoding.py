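"""Tokenizer, skip-gram embedding and k-mer frequency encoder."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rnaloc import encoding as enc
from rnaloc.encoding import (
    UNK,
    EmbeddingTable,
    SkipgramConfig,
    TokenizerConfig,
    all_kmers,
    embed_tokens,
    kmer_frequency_features,
    kmer_index,
    pool_sequence_vector,
    segment,
    train_skipgram,
)


class TestSegment:
    def test_hand_examples(self):
        assert segment("ATGGC") == ["ATG", "TGG", "GGC"]
        assert segment("ACG") == ["ACG"]

    def test_n_windows_become_unk(self):
        assert segment("ANGTC") == [UNK, UNK, "GTC"]

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="shorter than window"):
            segment("AC", TokenizerConfig(k=3))

    def test_stride_must_be_one(self):
        with pytest.raises(ValueError):
            TokenizerConfig(k=3, step=2)

    @settings(max_examples=50, deadline=None)
    @given(
        st.text(alphabet="ACGTN", min_size=1, max_size=200),
        st.integers(min_value=1, max_value=4),
    )
    def test_token_count_is_length_minus_k_plus_one(self, seq, k):
        if len(seq) < k:
            with pytest.raises(ValueError):
                segment(seq, TokenizerConfig(k=k))
        else:
            tokens = segment(seq, TokenizerConfig(k=k))
            assert len(tokens) == len(seq) - k + 1
            assert all(tok == UNK or len(tok) == k for tok in tokens)


def _template_corpus(n=300, seed=0):
    """AAA and CCC always share contexts; GGG lives in disjoint contexts."""
    rng = np.random.default_rng(seed)
    corpus = []
    shared = ["ATA", "TAT", "CGC", "GCG"]
    other = ["TTG", "TGT", "ACA", "CAC"]
    for _ in range(n):
        a, b = rng.choice(shared, size=2, replace=False)
        center = rng.choice(["AAA", "CCC"])
        corpus.append([a, str(center), b])
        a, b = rng.choice(other, size=2, replace=False)
        corpus.append([a, "GGG", b])
    return corpus


@pytest.fixture(scope="module")
def small_corpus():
    rng = np.random.default_rng(5)
    kmers = all_kmers(3)
    return [[kmers[j] for j in rng.integers(0, 64, size=30)] for _ in range(40)]


class TestSkipgram:
    @pytest.mark.parametrize("negative", [5, 0], ids=["neg-sampling", "softmax"])
    def test_full_vocab_shape(self, small_corpus, negative):
        cfg = SkipgramConfig(dim=16, context=2, epochs=1, negative=negative, seed=0)
        table = train_skipgram(small_corpus, cfg)
        assert len(table.vocabulary) == 64
        assert table.vectors.shape == (65, 16)
        norms = np.linalg.norm(table.vectors[1:], axis=1)
        assert np.isfinite(norms).all() and (norms > 0).all()

    def test_deterministic_given_seed(self, small_corpus):
        cfg = SkipgramConfig(dim=8, context=2, epochs=2, seed=11)
        t1 = train_skipgram(small_corpus, cfg)
        t2 = train_skipgram(small_corpus, cfg)
        np.testing.assert_array_equal(t1.vectors, t2.vectors)
        assert t1.tokens == t2.tokens

    @pytest.mark.parametrize("seed", range(5))
    def test_shared_contexts_give_higher_similarity(self, seed):
        corpus = _template_corpus(seed=seed)
        cfg = SkipgramConfig(
            dim=16, context=1, epochs=40, negative=5, batch=128, seed=seed
        )
        table = train_skipgram(corpus, cfg)

        def cos(a, b):
            va, vb = table.vector(a), table.vector(b)
            return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

        assert cos("AAA", "CCC") > cos("AAA", "GGG")

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty corpus"):
            train_skipgram([], SkipgramConfig(dim=4))

    def test_unk_row_stays_zero(self):
        corpus = [[UNK, "AAA", "AAC", UNK, "AAA"]] * 5
        table = train_skipgram(corpus, SkipgramConfig(dim=4, context=1, epochs=2))
        np.testing.assert_array_equal(table.vector(UNK), np.zeros(4))

    def test_round_trip_save_load(self, small_corpus, tmp_path):
        table = train_skipgram(
            small_corpus, SkipgramConfig(dim=6, context=2, epochs=1, seed=3)
        )
        table.save(tmp_path / "emb")
        back = EmbeddingTable.load(tmp_path / "emb")
        assert back.tokens == table.tokens and back.k == table.k
        np.testing.assert_allclose(back.vectors, table.vectors, atol=1e-12)


class TestLookupAndPooling:
    @pytest.fixture
    def table(self):
        tokens = [UNK, "AAA", "CCC", "GGG"]
        vectors = np.array(
            [[0.0, 0.0], [1.0, 2.0], [-1.0, -2.0], [3.0, 0.5]]
        )
        return EmbeddingTable(tokens, vectors, k=3)

    def test_embed_is_identity_lookup(self, table):
        mat = embed_tokens(["AAA", "GGG", "AAA"], table)
        assert mat.shape == (3, 2)
        np.testing.assert_array_equal(mat[0], table.vector("AAA"))
        np.testing.assert_array_equal(mat[1], table.vector("GGG"))
        np.testing.assert_array_equal(mat[0], mat[2])

    def test_oov_uses_unk_row(self, table):
        mat = embed_tokens(["TTT"], table)
        np.testing.assert_array_equal(mat[0], table.vector(UNK))

    def test_pool_single_token(self, table):
        np.testing.assert_array_equal(
            pool_sequence_vector(["AAA"], table), table.vector("AAA")
        )

    def test_pool_symmetric_vectors_cancel(self, table):
        np.testing.assert_allclose(
            pool_sequence_vector(["AAA", "CCC"], table), np.zeros(2), atol=1e-15
        )

    def test_pool_hand_mean(self, table):
        expected = (table.vector("AAA") + table.vector("CCC") + table.vector("GGG")) / 3
        np.testing.assert_allclose(
            pool_sequence_vector(["AAA", "CCC", "GGG"], table), expected
        )

    def test_standardized_centers_vocabulary(self, table):
        std = table.standardized()
        vocab_rows = std.vectors[1:]
        np.testing.assert_allclose(vocab_rows.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(vocab_rows.std(axis=0), 1.0, atol=1e-6)
        np.testing.assert_array_equal(std.vector(UNK), np.zeros(2))


class TestKmerFrequency:
    def test_hand_count(self):
        vec = kmer_frequency_features(segment("ATGGC"), 3)
        assert vec.shape == (64,)
        nonzero = {i: v for i, v in enumerate(vec) if v > 0}
        assert nonzero == {
            kmer_index("ATG"): pytest.approx(1 / 3),
            kmer_index("TGG"): pytest.approx(1 / 3),
            kmer_index("GGC"): pytest.approx(1 / 3),
        }

    def test_homopolymer(self):
        vec = kmer_frequency_features(segment("AAAA"), 3)
        assert vec[kmer_index("AAA")] == 1.0
        assert vec.sum() == 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=3, max_size=100))
    def test_probability_vector(self, seq):
        vec = kmer_frequency_features(segment(seq), 3)
        assert (vec >= 0).all()
        assert vec.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_unk_rejected(self):
        with pytest.raises(ValueError, match="UNK"):
            kmer_frequency_features([UNK, UNK], 3)
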