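from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegwords.cbow import (
    CBOWConfig,
    VocabularyError,
    build_huffman,
    cbow_objective,
    context_of,
    count_frequencies,
    export_embeddings,
    hs_gradients,
    hs_log_prob,
    train_cbow,
    CBOWModel,
)
from eegwords.translation import EEGSentence


def random_model(seed, vocab, d=4, k=2):
    """Untrained model with random parameters over a uniform-ish vocab."""
    rng = np.random.default_rng(seed)
    freqs = {w: int(f) for w, f in enumerate(rng.integers(1, 50, vocab))}
    tree = build_huffman(freqs)
    return CBOWModel(
        embeddings=rng.normal(size=(vocab, d)),
        node_vectors=rng.normal(size=(tree.n_internal, d)),
        tree=tree,
        freqs=freqs,
        config=CBOWConfig(d=d, k=k),
    )


class TestHuffman:
    def test_textbook_table(self):
        tree = build_huffman({0: 5, 1: 2, 2: 1, 3: 1})
        assert {w: len(c) for w, c in tree.codes.items()} == {0: 1, 1: 2, 2: 3, 3: 3}

    def test_two_words(self):
        tree = build_huffman({0: 3, 1: 9})
        assert all(len(c) == 1 for c in tree.codes.values())
        assert tree.n_internal == 1

    def test_single_word_empty_code(self):
        tree = build_huffman({7: 4})
        assert tree.codes == {7: []}

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            build_huffman({})

    def test_deterministic_under_ties(self):
        freqs = {w: 1 for w in range(8)}
        a, b = build_huffman(freqs), build_huffman(freqs)
        assert a.codes == b.codes

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 200), min_size=1, max_size=40))
    def test_kraft_equality_and_monotonicity(self, counts):
        freqs = dict(enumerate(counts))
        tree = build_huffman(freqs)
        assert sum(Fraction(1, 2 ** len(c)) for c in tree.codes.values()) == 1
        for w1 in freqs:
            for w2 in freqs:
                if freqs[w1] > freqs[w2]:
                    assert tree.code_length(w1) <= tree.code_length(w2)


class TestContext:
    def test_symmetric_window(self):
        assert context_of(EEGSentence([1, 2, 3, 4, 5]), 2, 2) == [1, 2, 4, 5]

    def test_small_window(self):
        assert context_of(EEGSentence([7, 8, 9]), 1, 1) == [7, 9]

    def test_boundary_rejected(self):
        with pytest.raises(IndexError):
            context_of(EEGSentence([7, 8, 9]), 0, 1)


class TestHierarchicalSoftmax:
    def test_single_word_is_certain(self):
        m = random_model(0, 1)
        assert hs_log_prob(m, [0, 0], 0) == 0.0

    def test_two_words_complementary(self):
        m = random_model(1, 2)
        ctx = [0, 1]
        total = np.exp(hs_log_prob(m, ctx, 0)) + np.exp(hs_log_prob(m, ctx, 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("vocab", [3, 17, 64])
    def test_leaf_probabilities_sum_to_one(self, vocab):
        m = random_model(vocab, vocab)
        ctx = list(np.random.default_rng(0).integers(0, vocab, 4))
        total = sum(np.exp(hs_log_prob(m, ctx, w)) for w in range(vocab))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_unknown_word_rejected(self):
        m = random_model(0, 4)
        with pytest.raises(VocabularyError):
            hs_log_prob(m, [0, 1], 99)

    def test_gradients_match_finite_differences(self):
        """Exact step gradients vs central differences of hs_log_prob."""
        m = random_model(5, 12, d=4, k=2)
        ctx, target = [3, 7, 1, 9], 5
        _, grad_h, node_grads = hs_gradients(m, ctx, target)
        eps = 1e-6
        # internal-node parameters
        for node, g in node_grads.items():
            for j in range(m.config.d):
                old = m.node_vectors[node, j]
                m.node_vectors[node, j] = old + eps
                lp = hs_log_prob(m, ctx, target)
                m.node_vectors[node, j] = old - eps
                lm = hs_log_prob(m, ctx, target)
                m.node_vectors[node, j] = old
                assert (lp - lm) / (2 * eps) == pytest.approx(g[j], abs=1e-5)
        # embedding rows: with averaging each context row sees grad_h / |ctx|
        w = ctx[0]
        mult = ctx.count(w)
        for j in range(m.config.d):
            old = m.embeddings[w, j]
            m.embeddings[w, j] = old + eps
            lp = hs_log_prob(m, ctx, target)
            m.embeddings[w, j] = old - eps
            lm = hs_log_prob(m, ctx, target)
            m.embeddings[w, j] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(
                mult * grad_h[j] / len(ctx), abs=1e-5
            )


class TestObjective:
    def test_never_positive(self):
        m = random_model(3, 10)
        sents = [EEGSentence(list(np.random.default_rng(1).integers(0, 10, 50)))]
        assert cbow_objective(m, sents) <= 0.0

    def test_single_word_vocabulary_is_zero(self):
        m = random_model(0, 1)
        assert cbow_objective(m, [EEGSentence([0] * 10)]) == 0.0

    def test_no_positions_warns_zero(self):
        m = random_model(0, 4, k=2)
        with pytest.warns(UserWarning):
            assert cbow_objective(m, [EEGSentence([1, 2])]) == 0.0


class TestTraining:
    def corpus(self, seed=0, vocab=12, n=400):
        rng = np.random.default_rng(seed)
        return [EEGSentence(list(rng.integers(0, vocab, n)))]

    def test_deterministic_given_seed(self):
        sents = self.corpus()
        cfg = CBOWConfig(d=6, k=2, epochs=2, seed=5)
        m1 = train_cbow(sents, cfg)
        m2 = train_cbow(sents, cfg)
        np.testing.assert_array_equal(m1.embeddings, m2.embeddings)
        np.testing.assert_array_equal(m1.node_vectors, m2.node_vectors)

    def test_objective_improves_with_training(self):
        """On a corpus with real structure the context objective rises."""
        rng = np.random.default_rng(2)
        # structured corpus: word pairs (2i, 2i+1) always adjacent
        ids = []
        for _ in range(300):
            i = int(rng.integers(0, 5))
            ids += [2 * i, 2 * i + 1]
        sents = [EEGSentence(ids)]
        cfg = CBOWConfig(d=8, k=2, epochs=0, seed=1)
        init = train_cbow(sents, cfg)
        trained = train_cbow(sents, CBOWConfig(d=8, k=2, epochs=10, seed=1))
        assert cbow_objective(trained, sents) > cbow_objective(init, sents)

    def test_predictive_word_recovery(self):
        """If word 3 always follows word 2, the trained model ranks 3 as
        the most likely center between 2 and the trailing filler."""
        rng = np.random.default_rng(4)
        ids = []
        for _ in range(400):
            ids += [int(rng.integers(5, 10)), 2, 3, int(rng.integers(5, 10))]
        sents = [EEGSentence(ids)]
        m = train_cbow(sents, CBOWConfig(d=8, k=1, epochs=10, seed=0))
        # center between 2 and a filler word: target 3 should win
        probs = {w: hs_log_prob(m, [2, 7], w) for w in m.tree.codes}
        assert max(probs, key=probs.get) == 3

    def test_vocab_size_covers_unseen_words(self):
        sents = [EEGSentence([0, 1, 2, 0, 1, 2, 0, 1, 2])]
        m = train_cbow(sents, CBOWConfig(d=4, k=1, epochs=1, seed=0), vocab_size=10)
        assert m.word_vector(9).shape == (4,)
        with pytest.raises(VocabularyError):
            m.word_vector(10)

    def test_untrained_rows_keep_seeded_init(self):
        sents = [EEGSentence([0, 1, 2, 0, 1, 2])]
        cfg = CBOWConfig(d=4, k=1, epochs=3, seed=9)
        m = train_cbow(sents, cfg, vocab_size=6)
        rng = np.random.default_rng(9)
        init = (rng.random((6, 4)) - 0.5) / 4
        np.testing.assert_array_equal(m.embeddings[5], init[5])  # never in corpus
        assert not np.array_equal(m.embeddings[1], init[1])      # trained

    def test_corpus_too_small_rejected(self):
        with pytest.raises(ValueError):
            train_cbow([EEGSentence([1, 2])], CBOWConfig(d=4, k=2, epochs=1))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        sents = [EEGSentence(list(np.random.default_rng(0).integers(0, 8, 100)))]
        m = train_cbow(sents, CBOWConfig(d=5, k=2, epochs=2, seed=1))
        m.save(tmp_path / "cbow.model")
        back = CBOWModel.load(tmp_path / "cbow.model")
        np.testing.assert_array_equal(back.embeddings, m.embeddings)
        np.testing.assert_array_equal(back.node_vectors, m.node_vectors)
        assert back.tree.codes == m.tree.codes
        assert hs_log_prob(back, [1, 2, 3, 4], 0) == hs_log_prob(m, [1, 2, 3, 4], 0)

    def test_export_plain_text(self, tmp_path):
        sents = [EEGSentence(list(np.random.default_rng(0).integers(0, 6, 60)))]
        m = train_cbow(sents, CBOWConfig(d=3, k=1, epochs=1, seed=0))
        path = tmp_path / "emb.txt"
        export_embeddings(m, path)
        lines = path.read_text().splitlines()
        assert lines[0] == f"{m.vocab_size} 3"
        assert len(lines) == m.vocab_size + 1
        first = lines[1].split()
        assert first[0] == "0" and len(first) == 4
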