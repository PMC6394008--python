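"""Keyword feature strategies for the free-text side of the model.

Three ways to turn a corpus of tokenized clinical documents into per-month
text features that can be concatenated onto the structured monthly
vectors:

1. **Frequency**: the top-n most frequent content words (stop-words
   excluded) become count features.
2. **Entropy**: words are ranked by the Kullback-Leibler divergence
   between their pooled temporal frequency distribution over
   months-to-death (1..50) and a reference distribution; the n words
   with the *lowest* divergence from the reference are selected. With the
   default late-mass reference (mass growing linearly toward death) this
   favours words whose usage profile grows as death approaches.
3. **Embedding**: a skip-gram word2vec model (negative sampling) is
   trained on the corpus and a month's text is represented by the mean of
   its word vectors.

Keyword-count features are normalized like a ninth feature category
(max-division per month); embedding means are passed through unchanged.
"""

from __future__ import annotations


from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .feature_engineering import MonthlyVector, N_MONTHS
from .text_pipeline import TokenizedDocument

__all__ = [
    "TemporalWordDistribution",
    "KeywordScore",
    "EmbeddingConfig",
    "MonthTextFeatures",
    "load_default_stopwords",
    "late_mass_reference",
    "uniform_reference",
    "temporal_distributions",
    "rank_by_frequency",
    "kl_score",
    "select_keywords",
    "SkipGramModel",
    "train_embeddings",
    "embed_month_text",
    "keyword_count_features",
    "embedding_features",
    "assemble_features",
]

HORIZON = 50


def load_default_stopwords() -> set[str]:
    data = resources.files("lifehorizon") / "data" / "stopwords.txt"
    return {
        w.strip()
        for w in data.read_text(encoding="utf-8").splitlines()
        if w.strip() and not w.startswith("#")
    }


@dataclass
class TemporalWordDistribution:
    """Pooled frequency distribution of a word over months-to-death 1..50."""

    word: str
    probabilities: np.ndarray  # length 50, sums to 1

    def __post_init__(self) -> None:
        if self.probabilities.shape != (HORIZON,):
            raise ValueError("temporal distribution must have 50 bins")
        if abs(float(self.probabilities.sum()) - 1.0) > 1e-9:
            raise ValueError("temporal distribution must sum to 1")


@dataclass(frozen=True)
class KeywordScore:
    word: str
    score: float  # KL divergence in nats, >= 0


@dataclass
class EmbeddingConfig:
    """Skip-gram hyperparameters (min_count 10, window 5, 300 dims)."""

    dimensions: int = 300
    min_count: int = 10
    context_window: int = 5
    epochs: int = 5
    negative_samples: int = 5
    learning_rate: float = 0.025

    def __post_init__(self) -> None:
        if self.dimensions not in (100, 200, 300):
            raise ValueError("dimensions must be one of 100, 200, 300")


@dataclass
class MonthTextFeatures:
    month: int  # 1..61
    vector: np.ndarray


def late_mass_reference() -> np.ndarray:
    """Reference with mass growing linearly toward death over 1..50 months out.

    ``reference_m`` is proportional to ``51 - m`` for months-to-death m,
    encoding that a prognostically relevant word is used more the closer
    death is.
    """
    weights = np.arange(HORIZON, 0, -1, dtype=float)  # m=1 -> 50, m=50 -> 1
    return weights / weights.sum()


def uniform_reference() -> np.ndarray:
    return np.full(HORIZON, 1.0 / HORIZON)


def temporal_distributions(
    corpus: list[TokenizedDocument], smoothing: float = 1.0
) -> dict[str, TemporalWordDistribution]:
    """Pool word counts by months-to-death and normalize per word.

    Documents are pooled across patients by their death-anchored month
    (months-to-death ``61 - source_month``; documents within 50 months of
    death only). An additive pseudo-count of ``smoothing`` per bin avoids
    zero bins before KL scoring.
    """
    counts: dict[str, np.ndarray] = {}
    for doc in corpus:
        mtd = N_MONTHS - doc.source_month
        if not (1 <= mtd <= HORIZON):
            continue
        for tok in doc.tokens:
            if tok not in counts:
                counts[tok] = np.zeros(HORIZON)
            counts[tok][mtd - 1] += 1
    out = {}
    for word, vec in counts.items():
        smoothed = vec + smoothing
        out[word] = TemporalWordDistribution(word, smoothed / smoothed.sum())
    return out


def _content_word_counts(
    corpus: list[TokenizedDocument], stopwords: set[str] | None
) -> Counter:
    stop = load_default_stopwords() if stopwords is None else stopwords
    counts: Counter = Counter()
    for doc in corpus:
        counts.update(tok for tok in doc.tokens if tok not in stop)
    return counts


def rank_by_frequency(
    corpus: list[TokenizedDocument], n: int, stopwords: set[str] | None = None
) -> list[str]:
    """Top-n content words by corpus frequency (ties lexicographic)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    counts = _content_word_counts(corpus, stopwords)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [w for w, _ in ranked[:n]]


def kl_score(dist: TemporalWordDistribution, reference: np.ndarray) -> KeywordScore:
    """KL divergence sum_m p_m ln(p_m / q_m); zero p-terms contribute 0."""
    p = dist.probabilities
    q = np.asarray(reference, dtype=float)
    if abs(float(q.sum()) - 1.0) > 1e-9:
        raise ValueError("reference must sum to 1")
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ZeroDivisionError(
            f"infinite divergence for {dist.word!r}: reference has zero mass "
            "where the word has support (apply smoothing)"
        )
    score = float(np.sum(p[mask] * np.log(p[mask] / q[mask])))
    return KeywordScore(dist.word, max(score, 0.0))


def select_keywords(
    corpus: list[TokenizedDocument],
    method: str,
    n: int,
    reference: np.ndarray | None = None,
    stopwords: set[str] | None = None,
    smoothing: float = 1.0,
) -> list[str]:
    """Select n keywords by ``"frequency"`` or ``"entropy"``.

    Entropy selection ranks ascending by KL divergence against
    ``reference`` (default: the late-mass reference); ties are broken by
    higher frequency, then lexicographically.
    """
    method = method.lower()
    if method == "frequency":
        return rank_by_frequency(corpus, n, stopwords)
    if method != "entropy":
        raise ValueError(f"unknown keyword selection method {method!r}")
    if n == 0:
        return []
    ref = late_mass_reference() if reference is None else reference
    counts = _content_word_counts(corpus, stopwords)
    dists = temporal_distributions(corpus, smoothing=smoothing)
    scored = [
        (kl_score(dists[w], ref).score, -counts[w], w)
        for w in counts
        if w in dists
    ]
    scored.sort()
    return [w for _, _, w in scored[:n]]


# ---------------------------------------------------------------------------
# Skip-gram word embeddings


class SkipGramModel:
    """Word vectors from skip-gram training; ``model[word]`` -> d-vector."""

    def __init__(self, vectors: dict[str, np.ndarray], dimensions: int):
        self.vectors = vectors
        self.dimensions = dimensions

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __getitem__(self, word: str) -> np.ndarray:
        return self.vectors[word]

    def __len__(self) -> int:
        return len(self.vectors)

    def save_text(self, path: str | Path) -> None:
        """Write the standard word2vec text format (word + d floats per line)."""
        words = sorted(self.vectors)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{len(words)} {self.dimensions}\n")
            for w in words:
                vals = " ".join(f"{x:.6f}" for x in self.vectors[w])
                fh.write(f"{w} {vals}\n")

    @classmethod
    def load_text(cls, path: str | Path) -> "SkipGramModel":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        _, d = lines[0].split()
        vectors = {}
        for line in lines[1:]:
            parts = line.split()
            vectors[parts[0]] = np.array([float(x) for x in parts[1:]])
        return cls(vectors, int(d))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def train_embeddings(
    corpus: list[TokenizedDocument], config: EmbeddingConfig, seed: int
) -> SkipGramModel:
    """Train skip-gram embeddings with negative sampling (single-threaded,
    fully seeded, hence reproducible).

    Words with corpus frequency below ``min_count`` are excluded from the
    vocabulary. Negative samples are drawn from the unigram distribution
    raised to the 3/4 power, as is conventional for word2vec.
    """
    counts: Counter = Counter()
    for doc in corpus:
        counts.update(doc.tokens)
    vocab = sorted(w for w, c in counts.items() if c >= config.min_count)
    if not vocab:
        raise ValueError("corpus yields no vocabulary at this min_count")
    word_id = {w: i for i, w in enumerate(vocab)}
    V, d = len(vocab), config.dimensions

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, d)) - 0.5) / d
    W_out = np.zeros((V, d))

    freq = np.array([counts[w] for w in vocab], dtype=float) ** 0.75
    noise = freq / freq.sum()

    sentences = [
        [word_id[t] for t in doc.tokens if t in word_id] for doc in corpus
    ]
    sentences = [s for s in sentences if len(s) >= 2]
    if not sentences:
        raise ValueError("corpus too small: no document retains two vocabulary words")

    lr = config.learning_rate
    win = config.context_window
    k = config.negative_samples
    for _ in range(config.epochs):
        for sent in sentences:
            for pos, center in enumerate(sent):
                lo = max(0, pos - win)
                hi = min(len(sent), pos + win + 1)
                for ctx_pos in range(lo, hi):
                    if ctx_pos == pos:
                        continue
                    context = sent[ctx_pos]
                    negatives = rng.choice(V, size=k, p=noise)
                    targets = np.concatenate(([context], negatives))
                    labels = np.zeros(len(targets))
                    labels[0] = 1.0
                    v = W_in[center]
                    u = W_out[targets]
                    scores = _sigmoid(u @ v)
                    grad = (scores - labels)[:, None]
                    W_in[center] = v - lr * (grad * u).sum(axis=0)
                    W_out[targets] = u - lr * grad * v
    return SkipGramModel({w: W_in[word_id[w]].copy() for w in vocab}, d)


def embed_month_text(tokens: list[str], model: SkipGramModel) -> np.ndarray:
    """Mean of the vectors of in-vocabulary tokens; zero vector if none."""
    vecs = [model[t] for t in tokens if t in model]
    if not vecs:
        return np.zeros(model.dimensions)
    return np.mean(vecs, axis=0)


# ---------------------------------------------------------------------------
# Per-month text features and concatenation


def keyword_count_features(
    docs_by_month: dict[int, list[TokenizedDocument]], keywords: list[str]
) -> list[MonthTextFeatures]:
    """Per-month keyword counts over months 1..61 (a ninth feature category)."""
    kw_index = {w: i for i, w in enumerate(keywords)}
    out = []
    for month in range(1, N_MONTHS + 1):
        vec = np.zeros(len(keywords))
        for doc in docs_by_month.get(month, []):
            for tok in doc.tokens:
                i = kw_index.get(tok)
                if i is not None:
                    vec[i] += 1
        out.append(MonthTextFeatures(month, vec))
    return out


def embedding_features(
    docs_by_month: dict[int, list[TokenizedDocument]], model: SkipGramModel
) -> list[MonthTextFeatures]:
    """Per-month mean word vector of all tokens written that month."""
    out = []
    for month in range(1, N_MONTHS + 1):
        tokens = [t for doc in docs_by_month.get(month, []) for t in doc.tokens]
        out.append(MonthTextFeatures(month, embed_month_text(tokens, model)))
    return out


def assemble_features(
    structured: list[MonthlyVector],
    text: list[MonthTextFeatures] | None,
    normalize_counts: bool = True,
) -> list[MonthlyVector]:
    """Concatenate text features after the structured features per month.

    Keyword counts are max-normalized per month like any feature
    category (``normalize_counts=True``); embedding means should be
    passed with ``normalize_counts=False``. Structured values are
    preserved bit-exactly.
    """
    if text is None:
        return structured
    if len(text) != len(structured) or any(
        s.month != t.month for s, t in zip(structured, text)
    ):
        raise ValueError("structured and text features cover different months")
    out = []
    for s, t in zip(structured, text):
        vec = t.vector.astype(float)
        if normalize_counts and vec.size and vec.max() > 0:
            vec = vec / vec.max()
        out.append(MonthlyVector(s.month, np.concatenate([s.values, vec])))
    return out
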