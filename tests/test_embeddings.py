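"""Tokenizer, SGNS training, and the three superposition stages vs brute force."""

from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from engagekit.embeddings import (
    SgnsConfig,
    VectorStore,
    corpus_term_vectors,
    cosine,
    stage1_message_vectors,
    stage2_message_vectors,
    tokenize,
    train_background,
)
from engagekit.forum_model import Corpus, Message
from engagekit.synthetic_data import RICH_THEMES, neologism_token, theme_tokens


def _corpus(bodies: list[str], year=2013) -> Corpus:
    msgs = [
        Message(f"m{i}", f"t{i}", "u", None, datetime(year, 1, 1 + i % 27), b)
        for i, b in enumerate(bodies)
    ]
    return Corpus(messages=msgs)


class TestTokenize:
    def test_strips_punctuation_and_lowercases(self):
        assert tokenize("Nicodemon!!") == ["nicodemon"]

    def test_empty(self):
        assert tokenize("") == []

    def test_single_char_tokens_dropped(self):
        assert tokenize("I a m quitting") == ["quitting"]

    def test_stopwords_removed(self):
        assert tokenize("the smoke the", stopwords=frozenset({"the"})) == ["smoke"]

    @given(st.text(max_size=120))
    @settings(max_examples=80, derandomize=True)
    def test_idempotent(self, text):
        once = tokenize(text)
        assert tokenize(" ".join(once)) == once


class TestSgnsTraining:
    def test_cooccurring_terms_beat_median_pair(self):
        # "hammock" and "relaxing" always share a context window
        rng = np.random.default_rng(2)
        fillers = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta"]
        docs = []
        for _ in range(120):
            noise = list(rng.choice(fillers, size=6))
            docs.append(" ".join(["relaxing", "hammock"] + noise))
        store = train_background(docs, SgnsConfig(dimension=16, epochs=10, min_count=5, seed=0))
        sims = [
            store.cosine(a, b)
            for i, a in enumerate(store.ids)
            for b in store.ids[i + 1 :]
        ]
        assert store.cosine("hammock", "relaxing") > np.median(sims)

    def test_vocabulary_covers_retained_terms(self):
        docs = ["smoke free community forum today", "community forum people smoke daily"]
        store = train_background(docs, SgnsConfig(dimension=10, epochs=1, min_count=1, seed=0))
        vocab = {t for d in docs for t in tokenize(d)}
        assert set(store.ids) == vocab
        assert store.dimension == 10

    def test_empty_vocabulary_is_config_error(self):
        with pytest.raises(ValueError, match="vocabulary"):
            train_background(["one two"], SgnsConfig(dimension=8, min_count=5, seed=0))

    def test_seed_determinism(self):
        docs = [
            " ".join(c + "tok" for c in np.random.default_rng(i).choice(list("abcdefgh"), size=12))
            for i in range(60)
        ]
        cfg = SgnsConfig(dimension=12, epochs=2, min_count=1, seed=11)
        a = train_background(docs, cfg)
        b = train_background(docs, cfg)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_planted_paraphrase_pairs_rank_above_random(self, bundle):
        store = bundle.background
        pairs = [
            (a, b) for a, b in bundle.fixture.config.paraphrase_pairs()
            if a in store and b in store
        ]
        rng = np.random.default_rng(0)
        pos = [store.cosine(a, b) for a, b in pairs]
        idx = rng.integers(len(store.ids), size=(400, 2))
        neg = [store.cosine(store.ids[i], store.ids[j]) for i, j in idx if i != j]
        auc = roc_auc_score([1] * len(pos) + [0] * len(neg), pos + neg)
        assert auc >= 0.9


class TestVectorStore:
    def test_unit_norm_and_idempotent_normalize(self, bundle):
        for store in (bundle.background, bundle.stage1, bundle.terms, bundle.stage2):
            norms = np.linalg.norm(store.matrix, axis=1)
            nonzero = norms > 0
            assert np.allclose(norms[nonzero], 1.0, atol=1e-6)
            before = store.matrix.copy()
            store.normalize()
            np.testing.assert_allclose(store.matrix, before, atol=1e-12)

    def test_all_stages_dimension_match(self, bundle):
        dims = {s.dimension for s in (bundle.background, bundle.stage1, bundle.terms, bundle.stage2)}
        assert dims == {50}

    def test_self_similarity_and_bounds(self, bundle):
        store = bundle.terms
        rng = np.random.default_rng(1)
        for i in rng.integers(len(store.ids), size=30):
            t = store.ids[i]
            if t in store.flagged:
                continue
            assert store.cosine(t, t) == pytest.approx(1.0, abs=1e-6)
        for i, j in rng.integers(len(store.ids), size=(50, 2)):
            assert -1 - 1e-9 <= store.cosine(store.ids[i], store.ids[j]) <= 1 + 1e-9

    def test_save_load_round_trip(self, tmp_path):
        store = VectorStore(["aa", "bb"], np.array([[1.0, 2.0], [3.0, -4.0]]), "CORPUS_TERMS",
                            config=SgnsConfig(dimension=2), flagged={"bb"})
        p = tmp_path / "terms.vec"
        store.save(p)
        again = VectorStore.load(p)
        assert again.ids == store.ids
        assert again.provenance == "CORPUS_TERMS"
        assert again.flagged == {"bb"}
        assert again.config.dimension == 2
        np.testing.assert_array_equal(again.matrix, store.matrix)

    def test_unknown_provenance_rejected(self):
        with pytest.raises(ValueError, match="provenance"):
            VectorStore(["x"], np.zeros((1, 3)), "SOMETHING_ELSE")


class TestSuperpositionStages:
    @pytest.fixture()
    def tiny_background(self):
        ids = ["aa", "bb", "cc"]
        mat = np.array([[2.0, 0.0], [0.0, 2.0], [1.0, 1.0]])
        return VectorStore(ids, mat, "BACKGROUND_TERMS")

    def test_stage1_identity_and_oov(self, tiny_background):
        corpus = _corpus(["aa", "zz qq", "aa bb", "aa aa bb"])
        s1 = stage1_message_vectors(tiny_background, corpus)
        np.testing.assert_allclose(s1["m0"], [1.0, 0.0])
        assert np.all(s1["m1"] == 0) and s1.flagged == {"m1"}
        np.testing.assert_allclose(s1["m2"], np.array([2.0, 2.0]) / np.sqrt(8))
        # multiplicity counted: 2*aa + bb
        np.testing.assert_allclose(s1["m3"], np.array([4.0, 2.0]) / np.sqrt(20))

    def test_stage1_token_order_irrelevant(self, tiny_background):
        s1 = stage1_message_vectors(tiny_background, _corpus(["aa bb cc", "cc bb aa"]))
        np.testing.assert_array_equal(s1["m0"], s1["m1"])

    def test_term_stage_presence_semantics(self, tiny_background):
        # "aa aa" and "aa" must contribute identically per message
        corpus = _corpus(["aa aa bb", "aa bb"])
        s1 = stage1_message_vectors(tiny_background, corpus)
        terms = corpus_term_vectors(s1, corpus)
        brute_aa = s1["m0"] + s1["m1"]
        np.testing.assert_allclose(terms["aa"], brute_aa / np.linalg.norm(brute_aa))

    def test_term_in_single_message_is_that_message_vector(self, tiny_background):
        corpus = _corpus(["aa bb", "bb cc"])
        s1 = stage1_message_vectors(tiny_background, corpus)
        terms = corpus_term_vectors(s1, corpus)
        np.testing.assert_allclose(terms["aa"], s1["m0"] / np.linalg.norm(s1["m0"]))

    def test_stage2_single_token_identity(self, tiny_background):
        corpus = _corpus(["aa bb", "aa"])
        s1 = stage1_message_vectors(tiny_background, corpus)
        terms = corpus_term_vectors(s1, corpus)
        s2 = stage2_message_vectors(terms, corpus)
        np.testing.assert_allclose(s2["m1"], terms["aa"] / np.linalg.norm(terms["aa"]))

    def test_stage1_matches_brute_force(self, bundle):
        corpus = bundle.fixture.corpus
        background, s1 = bundle.background, bundle.stage1
        rng = np.random.default_rng(3)
        for i in rng.integers(len(corpus.messages), size=50):
            m = corpus.messages[i]
            vec = np.zeros(background.dimension)
            for tok in tokenize(m.body):
                if tok in background:
                    vec = vec + background[tok]
            norm = np.linalg.norm(vec)
            expected = vec / norm if norm > 0 else vec
            np.testing.assert_allclose(s1[m.message_id], expected, atol=1e-9)

    def test_term_vectors_match_inverted_index_brute_force(self, bundle):
        sub = Corpus(messages=bundle.fixture.corpus.messages[:100])
        s1 = stage1_message_vectors(bundle.background, sub)
        terms = corpus_term_vectors(s1, sub)
        inverted: dict[str, set[str]] = {}
        for m in sub.messages:
            for tok in set(tokenize(m.body)):
                inverted.setdefault(tok, set()).add(m.message_id)
        assert set(terms.ids) == set(inverted)
        rng = np.random.default_rng(4)
        for i in rng.integers(len(terms.ids), size=60):
            term = terms.ids[i]
            vec = np.zeros(terms.dimension)
            for mid in inverted[term]:
                vec = vec + s1[mid]
            norm = np.linalg.norm(vec)
            expected = vec / norm if norm > 0 else vec
            np.testing.assert_allclose(terms[term], expected, atol=1e-9)

    def test_stage2_matches_brute_force(self, bundle):
        corpus = bundle.fixture.corpus
        terms, s2 = bundle.terms, bundle.stage2
        rng = np.random.default_rng(5)
        for i in rng.integers(len(corpus.messages), size=50):
            m = corpus.messages[i]
            vec = np.zeros(terms.dimension)
            for tok in tokenize(m.body):
                if tok in terms:
                    vec = vec + terms[tok]
            norm = np.linalg.norm(vec)
            expected = vec / norm if norm > 0 else vec
            np.testing.assert_allclose(s2[m.message_id], expected, atol=1e-9)

    def test_superposition_additive_over_token_union(self, tiny_background):
        corpus = _corpus(["aa bb", "cc cc", "aa bb cc cc"])
        s1 = stage1_message_vectors(tiny_background, corpus)
        # pre-normalization additivity: reconstruct unnormalized sums
        def unnorm(body):
            vec = np.zeros(2)
            for tok in tokenize(body):
                if tok in tiny_background:
                    vec = vec + tiny_background[tok]
            return vec

        np.testing.assert_allclose(unnorm("aa bb cc cc"), unnorm("aa bb") + unnorm("cc cc"))
        combined = unnorm("aa bb cc cc")
        np.testing.assert_allclose(s1["m2"], combined / np.linalg.norm(combined))


class TestNeologismTransfer:
    def test_neologisms_gain_theme_aligned_vectors(self, bundle):
        terms = bundle.terms
        rng = np.random.default_rng(6)
        idx = rng.integers(len(terms.ids), size=(2000, 2))
        random_cos = np.array(
            [terms.cosine(terms.ids[i], terms.ids[j]) for i, j in idx if i != j]
        )
        threshold = np.percentile(random_cos, 95)
        for theme in RICH_THEMES:
            neo = neologism_token(theme)
            anchor = theme_tokens(theme)[0]
            assert neo in terms, "neologism must be covered at the corpus-term stage"
            assert neo not in bundle.background, "neologism must be background-OOV"
            assert terms.cosine(neo, anchor) > threshold

    def test_stage2_ties_disjoint_synonym_messages_tighter_than_stage1(self, bundle):
        # two messages with disjoint tokens whose vocabularies the forum
        # (not the background) makes synonymous via co-occurrence
        t0a, t0b = theme_tokens(RICH_THEMES[0])[0:2]
        t1a, t1b = theme_tokens(RICH_THEMES[1])[0:2]
        bodies = [f"{t0a} {t0b}", f"{t1a} {t1b}"] + [f"{t0a} {t1a}"] * 25
        corpus = _corpus(bodies)
        s1 = stage1_message_vectors(bundle.background, corpus)
        terms = corpus_term_vectors(s1, corpus)
        s2 = stage2_message_vectors(terms, corpus)
        assert cosine(s2["m0"], s2["m1"]) > cosine(s1["m0"], s1["m1"])
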