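"""Keyword selection (frequency / KL), skip-gram embeddings, assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lifehorizon.emr_data import DocType
from lifehorizon.feature_engineering import MonthlyVector
from lifehorizon.keyword_features import (
    EmbeddingConfig,
    SkipGramModel,
    TemporalWordDistribution,
    assemble_features,
    embed_month_text,
    keyword_count_features,
    kl_score,
    late_mass_reference,
    rank_by_frequency,
    select_keywords,
    temporal_distributions,
    train_embeddings,
    uniform_reference,
)
from lifehorizon.text_pipeline import TokenizedDocument


def _doc(tokens, month=55):
    return TokenizedDocument(DocType.NOTE, list(tokens), month)


def _corpus_from_counts(counts: dict[str, int]):
    return [_doc([w] * c) for w, c in counts.items()]


class TestFrequencyRanking:
    def test_top_n(self):
        corpus = _corpus_from_counts({"a": 5, "b": 3, "c": 1})
        assert rank_by_frequency(corpus, 2, stopwords=set()) == ["a", "b"]

    def test_tie_breaks_lexicographic(self):
        corpus = _corpus_from_counts({"b": 3, "a": 3})
        assert rank_by_frequency(corpus, 1, stopwords=set()) == ["a"]

    def test_n_larger_than_vocabulary(self):
        corpus = _corpus_from_counts({"a": 2, "b": 1})
        assert rank_by_frequency(corpus, 10, stopwords=set()) == ["a", "b"]

    def test_stopwords_excluded(self):
        corpus = _corpus_from_counts({"de": 50, "pijn": 3})
        assert rank_by_frequency(corpus, 1, stopwords={"de"}) == ["pijn"]

    def test_empty_corpus(self):
        assert rank_by_frequency([], 5, stopwords=set()) == []


class TestKLScore:
    def test_identical_distributions_score_zero(self):
        ref = uniform_reference()
        dist = TemporalWordDistribution("w", ref.copy())
        assert kl_score(dist, ref).score == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_is_ln_50(self):
        p = np.zeros(50)
        p[0] = 1.0
        dist = TemporalWordDistribution("w", p)
        assert kl_score(dist, uniform_reference()).score == pytest.approx(math.log(50))

    def test_zero_reference_support_raises(self):
        p = np.zeros(50)
        p[0] = 1.0
        q = np.zeros(50)
        q[1] = 1.0
        with pytest.raises(ZeroDivisionError):
            kl_score(TemporalWordDistribution("w", p), q)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_summation(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(50))
        q = rng.dirichlet(np.ones(50)) + 1e-6
        q /= q.sum()
        expected = sum(
            pi * math.log(pi / qi) for pi, qi in zip(p, q) if pi > 0
        )
        got = kl_score(TemporalWordDistribution("w", p), q).score
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-12)
        assert got >= 0


class TestTemporalDistributions:
    def test_pooled_by_months_to_death(self):
        # month 56 -> 5 months to death; month 31 -> 30 months to death
        corpus = [_doc(["w"], month=56), _doc(["w", "w"], month=31)]
        dists = temporal_distributions(corpus, smoothing=0.0)
        probs = dists["w"].probabilities
        assert probs[5 - 1] == pytest.approx(1 / 3)
        assert probs[30 - 1] == pytest.approx(2 / 3)

    def test_death_month_and_too_early_documents_ignored(self):
        corpus = [_doc(["w"], month=61), _doc(["w"], month=5), _doc(["w"], month=41)]
        dists = temporal_distributions(corpus, smoothing=0.0)
        assert dists["w"].probabilities[20 - 1] == 1.0


class TestEntropySelection:
    def test_planted_terminal_keyword_outranks_background(self):
        # keyword usage grows linearly toward death (the profile the
        # late-mass reference encodes); background word used uniformly.
        # Hand-computed: KL(keyword||ref) ~ 0 < KL(uniform||ref) ~ 0.27 nats.
        corpus = []
        for month in range(11, 61):
            mtd = 61 - month
            corpus.append(_doc(["achtergrond"], month=month))
            corpus.append(_doc(["hospice"] * (51 - mtd), month=month))
        ranked = select_keywords(corpus, "entropy", 2, late_mass_reference())
        assert ranked.index("hospice") < ranked.index("achtergrond")

    def test_frequency_ignores_temporal_pattern(self):
        corpus = [_doc(["a"] * 10, month=20), _doc(["b"] * 3, month=58)]
        assert select_keywords(corpus, "frequency", 2, stopwords=set()) == ["a", "b"]

    def test_n_zero(self):
        assert select_keywords([_doc(["a"])], "entropy", 0) == []


@pytest.fixture(scope="module")
def corpus():
    rng = np.random.default_rng(0)
    words = [f"w{i}" for i in range(12)]
    docs = []
    for _ in range(60):
        toks = [words[int(i)] for i in rng.integers(0, len(words), 30)]
        docs.append(_doc(toks))
    docs.append(_doc(["zeldzaam"] * 9))  # below min_count
    return docs


@pytest.fixture(scope="module")
def model(corpus):
    cfg = EmbeddingConfig(dimensions=100, epochs=2)
    return train_embeddings(corpus, cfg, seed=1)


class TestEmbeddings:

    def test_min_count_exclusion(self, model):
        assert "zeldzaam" not in model
        assert "w0" in model

    def test_vector_dimension(self, model):
        assert model["w0"].shape == (100,)

    def test_training_determinism(self, corpus):
        cfg = EmbeddingConfig(dimensions=100, epochs=1)
        a = train_embeddings(corpus, cfg, seed=7)
        b = train_embeddings(corpus, cfg, seed=7)
        assert all(np.array_equal(a[w], b[w]) for w in a.vectors)

    def test_dimension_restricted_to_standard_sizes(self):
        with pytest.raises(ValueError):
            EmbeddingConfig(dimensions=64)

    def test_empty_corpus_is_error(self):
        with pytest.raises(ValueError):
            train_embeddings([_doc(["once"])], EmbeddingConfig(dimensions=100), 0)

    def test_text_format_round_trip(self, model, tmp_path):
        model.save_text(tmp_path / "vectors.txt")
        again = SkipGramModel.load_text(tmp_path / "vectors.txt")
        assert len(again) == len(model)
        np.testing.assert_allclose(again["w0"], model["w0"], atol=1e-6)


class TestEmbedMonthText:
    def _model(self):
        return SkipGramModel({"a": np.array([1.0, 3.0]), "b": np.array([3.0, 5.0])}, 2)

    def test_repeated_word_is_its_vector(self):
        model = self._model()
        np.testing.assert_array_equal(embed_month_text(["a", "a", "a"], model), model["a"])

    def test_empty_tokens_zero_vector(self):
        assert embed_month_text([], self._model()).tolist() == [0.0, 0.0]

    def test_mean_of_two_words(self):
        np.testing.assert_array_equal(
            embed_month_text(["a", "b"], self._model()), np.array([2.0, 4.0])
        )

    @given(perm=st.permutations(["a", "b", "a", "b", "b"]))
    @settings(max_examples=20, deadline=None)
    def test_permutation_invariance(self, perm):
        model = self._model()
        np.testing.assert_allclose(
            embed_month_text(list(perm), model),
            embed_month_text(["a", "a", "b", "b", "b"], model),
        )


class TestAssembleFeatures:
    def _structured(self, dim=4):
        return [MonthlyVector(m, np.full(dim, 0.25)) for m in range(1, 62)]

    def test_dimensions_add(self):
        text = keyword_count_features({}, ["x", "y", "z"])
        out = assemble_features(self._structured(4), text)
        assert out[0].values.shape == (7,)

    def test_structured_values_preserved_bit_exactly(self):
        structured = self._structured()
        docs = {55: [_doc(["x", "x", "y"], 55)]}
        text = keyword_count_features(docs, ["x", "y"])
        out = assemble_features(structured, text)
        for s, o in zip(structured, out):
            np.testing.assert_array_equal(o.values[:4], s.values)

    def test_keyword_counts_max_normalized_per_month(self):
        docs = {55: [_doc(["x", "x", "y"], 55)]}
        text = keyword_count_features(docs, ["x", "y"])
        out = assemble_features(self._structured(1), text)
        assert out[54].values[1:].tolist() == [1.0, 0.5]

    def test_none_text_returns_structured(self):
        structured = self._structured()
        assert assemble_features(structured, None) is structured

    def test_month_mismatch_is_error(self):
        text = keyword_count_features({}, ["x"])
        with pytest.raises(ValueError, match="month"):
            assemble_features(self._structured()[:-1], text)
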