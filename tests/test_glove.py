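"""Co-occurrence construction and the GloVe objective against oracles."""

import math

import numpy as np
import pytest

from deepmethyl import (
    GloveConfig,
    GloveParams,
    KmerVocabulary,
    TokenizedCorpus,
    ValidationError,
    build_cooccurrence,
    build_vocab,
    fit_glove,
    glove_grad,
    glove_loss,
    glove_weight,
    load_embedding,
    save_embedding,
    tokenize_corpus,
)
from deepmethyl.errors import ParseError
from deepmethyl.synthetic import SyntheticSpec, generate


def cooccurrence_bruteforce(docs, n, window):
    """Exhaustive enumeration of all in-window ordered pairs, mirrored."""
    X = np.zeros((n, n))
    for doc in docs:
        for p in range(len(doc)):
            for s in range(1, window + 1):
                if p + s < len(doc):
                    X[doc[p], doc[p + s]] += 1
                    X[doc[p + s], doc[p]] += 1
    return X


def _corpus_from_ids(docs, n_tokens):
    vocab = KmerVocabulary.full(3)
    vocab = KmerVocabulary(k=3, tokens=vocab.tokens[:n_tokens])
    return TokenizedCorpus(
        documents=[np.asarray(d, dtype=np.int64) for d in docs], vocab=vocab
    )


class TestCooccurrence:
    @pytest.mark.parametrize("window", [1, 2, 3])
    def test_matches_bruteforce_on_random_corpora(self, window, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            docs = [
                rng.integers(0, n, size=rng.integers(1, 15)).tolist()
                for _ in range(int(rng.integers(1, 20)))
            ]
            corpus = _corpus_from_ids(docs, n)
            X = build_cooccurrence(corpus, window=window)
            np.testing.assert_array_equal(X.X, cooccurrence_bruteforce(docs, n, window))
            np.testing.assert_array_equal(X.X, X.X.T)

    def test_adjacent_pair_counted_twice_is_two_both_ways(self):
        # 'CGG' immediately precedes 'ATC' in two documents
        vocab = KmerVocabulary(k=3, tokens=["CGG", "ATC", "TTT"])
        docs = [[0, 1, 2], [2, 0, 1]]
        corpus = TokenizedCorpus([np.array(d) for d in docs], vocab)
        X = build_cooccurrence(corpus, window=1)
        assert X.count("CGG", "ATC") == 2
        assert X.count("ATC", "CGG") == 2

    def test_single_token_documents_give_zero_matrix(self):
        corpus = _corpus_from_ids([[0], [1], [2]], 3)
        assert build_cooccurrence(corpus, window=1).X.sum() == 0

    def test_empty_corpus_rejected(self):
        vocab = KmerVocabulary(k=3, tokens=["AAA"])
        with pytest.raises(ValidationError):
            build_cooccurrence(TokenizedCorpus([], vocab), window=1)

    def test_counts_are_integers_without_distance_weighting(self, rng):
        corpus = _corpus_from_ids([rng.integers(0, 5, size=20).tolist()], 5)
        X = build_cooccurrence(corpus, window=3)
        np.testing.assert_array_equal(X.X, np.round(X.X))


class TestWeighting:
    def test_at_or_above_truncation_is_one(self):
        assert glove_weight(100.0, T_X=100.0) == 1.0
        assert glove_weight(1e6, T_X=100.0) == 1.0

    def test_closed_form_power(self):
        # (1/16)^(3/4) = 2^-3
        assert glove_weight(100.0 / 16, T_X=100.0, alpha=0.75) == pytest.approx(0.125)

    def test_zero_count_gets_zero_weight(self):
        assert glove_weight(0.0) == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            glove_weight(-1.0)

    def test_nondecreasing_and_continuous_at_truncation(self):
        xs = np.linspace(0, 200, 2001)
        fx = glove_weight(xs, T_X=100.0, alpha=0.75)
        assert (np.diff(fx) >= -1e-12).all()
        assert glove_weight(100.0 - 1e-9) == pytest.approx(1.0, abs=1e-8)
        assert (fx >= 0).all() and (fx <= 1).all()


def _two_token_instance():
    X = np.array([[0.0, 4.0], [4.0, 0.0]])
    cfg = GloveConfig(d=2, T_X=100.0, alpha=0.75, seed=0)
    return X, cfg


class TestLossAndGradient:
    def test_zero_residual_gives_zero_loss(self):
        X, cfg = _two_token_instance()
        b = np.full(2, math.log(4.0) / 2)  # b_i + b_j = log 4
        params = GloveParams(V=np.zeros((2, 2)), V_tilde=np.zeros((2, 2)),
                             b=b, b_tilde=b.copy())
        assert glove_loss(params, X, cfg) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_two_term_sum(self):
        X, cfg = _two_token_instance()
        params = GloveParams(V=np.zeros((2, 2)), V_tilde=np.zeros((2, 2)),
                             b=np.zeros(2), b_tilde=np.zeros(2))
        # direct scalar evaluation: two nonzero cells, each f(4) * (log 4)^2
        expected = 2 * (4.0 / 100.0) ** 0.75 * math.log(4.0) ** 2
        assert glove_loss(params, X, cfg) == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        X, cfg = _two_token_instance()
        params = GloveParams(V=np.zeros((3, 2)), V_tilde=np.zeros((3, 2)),
                             b=np.zeros(3), b_tilde=np.zeros(3))
        with pytest.raises(ValidationError):
            glove_loss(params, X, cfg)

    def test_analytic_gradient_matches_central_differences(self, rng):
        n, d = 5, 3
        X = rng.integers(0, 8, size=(n, n)).astype(float)
        X = X + X.T
        cfg = GloveConfig(d=d, seed=0)
        params = GloveParams.init(n, d, rng)
        # scale up so residuals are not vanishing
        params.V *= 20
        params.V_tilde *= 20
        grad = glove_grad(params, X, cfg)
        eps = 1e-6
        for arr, darr in [
            (params.V, grad.V), (params.V_tilde, grad.V_tilde),
            (params.b, grad.b), (params.b_tilde, grad.b_tilde),
        ]:
            flat, dflat = arr.ravel(), darr.ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                orig = flat[i]
                flat[i] = orig + eps
                lp = glove_loss(params, X, cfg)
                flat[i] = orig - eps
                lm = glove_loss(params, X, cfg)
                flat[i] = orig
                numeric = (lp - lm) / (2 * eps)
                denom = max(abs(numeric), abs(dflat[i]), 1e-8)
                assert abs(numeric - dflat[i]) / denom < 1e-5


class TestFit:
    def _small_matrix(self):
        ds = generate(SyntheticSpec(n_pos=20, n_neg=20, seed=3))
        vocab = build_vocab(ds, 3)
        corpus = tokenize_corpus(ds, vocab)
        return build_cooccurrence(corpus, window=1)

    def test_fixed_seed_is_bit_reproducible(self):
        X = self._small_matrix()
        cfg = GloveConfig(d=6, epochs=3, seed=42)
        a = fit_glove(X, cfg)
        b = fit_glove(X, cfg)
        np.testing.assert_array_equal(a.vectors, b.vectors)
        assert a.loss_history == b.loss_history

    def test_loss_decreases_and_is_recorded(self):
        X = self._small_matrix()
        emb = fit_glove(X, GloveConfig(d=6, epochs=10, seed=1))
        hist = emb.loss_history
        assert len(hist) == 11
        assert hist[-1] < hist[0]
        # per-epoch full loss non-increasing within stochastic-update slack
        assert all(b <= a * 1.01 + 1e-9 for a, b in zip(hist, hist[1:]))

    def test_embedding_table_shape(self):
        X = self._small_matrix()
        emb = fit_glove(X, GloveConfig(d=6, epochs=2, seed=1))
        assert emb.vectors.shape == (len(X.vocab), 6)

    def test_exactly_fittable_instance_reaches_zero_loss(self):
        vocab = KmerVocabulary(k=3, tokens=["AAA", "CCC"])
        from deepmethyl.glove import CooccurrenceMatrix

        X = CooccurrenceMatrix(
            X=np.array([[0.0, 4.0], [4.0, 0.0]]), vocab=vocab, window=1
        )
        emb = fit_glove(X, GloveConfig(d=2, epochs=800, seed=0))
        assert emb.loss_history[-1] < 1e-4

    def test_tokens_in_identical_contexts_embed_similarly(self, rng):
        # tokens 0 and 1 always appear between the same neighbours; they
        # should end up closer than typical random pairs
        n = 8
        docs = []
        for _ in range(150):
            mid = int(rng.integers(0, 2))
            left, right = int(rng.integers(2, 5)), int(rng.integers(5, 8))
            docs.append([left, mid, right])
        corpus = _corpus_from_ids(docs, n)
        X = build_cooccurrence(corpus, window=1)
        emb = fit_glove(X, GloveConfig(d=4, epochs=80, seed=0))
        V = emb.vectors

        def cos(i, j):
            return V[i] @ V[j] / (np.linalg.norm(V[i]) * np.linalg.norm(V[j]))

        others = [cos(i, j) for i in range(2, n) for j in range(i + 1, n)]
        assert cos(0, 1) > np.mean(others)


class TestEmbeddingIO:
    def test_round_trip_within_tolerance(self, tmp_path, tiny_embedding):
        path = tmp_path / "emb.txt"
        save_embedding(tiny_embedding, path)
        back = load_embedding(path)
        assert back.tokens == tiny_embedding.tokens
        np.testing.assert_allclose(back.vectors, tiny_embedding.vectors, atol=1e-6)

    def test_short_line_names_the_line(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("AAA 0.1 0.2\nCCC 0.3\n")
        with pytest.raises(ParseError, match="emb.txt:2"):
            load_embedding(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "emb.txt"
        path.write_text("")
        with pytest.raises(ParseError):
            load_embedding(path)
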