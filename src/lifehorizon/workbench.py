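"""Experiment orchestration: end-to-end runs, stepwise category selection,
and hyperparameter grid search.

``run_experiment`` executes the full pipeline — generate (or load) a
cohort, preprocess free text, build the structured feature vocabulary on
the development split, select keyword features, window the histories,
train the LSTM, and evaluate on the held-out recency split — and is
fully reproducible from the config's master seed. Per-stage seeds are
derived deterministically from the master seed so stages can be rerun in
isolation.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import evaluation, feature_engineering as fe, keyword_features as kw
from .emr_data import Cohort
from .lstm import LSTMClassifier, ModelConfig
from .synthetic_cohort import GeneratorConfig, generate_cohort
from .text_pipeline import LexiconSet, TokenizedDocument, load_default_lexicons, preprocess_document

__all__ = [
    "KeywordConfig",
    "EvaluationConfig",
    "ExperimentConfig",
    "stage_seed",
    "run_experiment",
    "stepwise_category_selection",
    "grid_search",
    "percent_reduction",
]

logger = logging.getLogger("lifehorizon")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return zlib.crc32(f"{stage}:{master}".encode()) & 0x7FFFFFFF


def percent_reduction(before: int, after: int) -> float:
    """Percent reduction of a feature set, e.g. 4649 -> 931 is 80%."""
    if before <= 0:
        raise ValueError("before must be positive")
    return round(100.0 * (before - after) / before)


@dataclass
class KeywordConfig:
    method: str | None = None  # None (baseline) | frequency | entropy | embedding
    n: int = 100  # keyword-set size (100 | 200 | 300)
    embedding: kw.EmbeddingConfig = field(default_factory=kw.EmbeddingConfig)
    reference: str = "late_mass"  # late_mass | uniform


@dataclass
class EvaluationConfig:
    test_fraction: float = 0.10
    k: int = 10


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    category_config: dict = field(
        default_factory=lambda: dict(fe.DEFAULT_CATEGORY_CONFIG)
    )
    keywords: KeywordConfig = field(default_factory=KeywordConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0
    output_dir: Path | None = None


# ---------------------------------------------------------------------------
# Pipeline pieces


def _preprocess_patient_docs(
    record, lexicons: LexiconSet
) -> dict[int, list[TokenizedDocument]]:
    """Tokenize all of a patient's documents, grouped by month index 1..61."""
    by_month: dict[int, list[TokenizedDocument]] = {}
    for cons in record.consultations:
        if not cons.documents:
            continue
        month = fe._month_bin(cons.date, record.death_date)
        for doc in cons.documents:
            tokdoc = preprocess_document(doc, month, lexicons)
            by_month.setdefault(month, []).append(tokdoc)
    return by_month


def _patient_windows(
    record,
    vocab: fe.FeatureVocabulary,
    category_config,
    text_featurizer=None,
    lexicons: LexiconSet | None = None,
) -> list[fe.WindowSample]:
    monthly = fe.bin_monthly(record, vocab, category_config)
    monthly = fe.normalize_monthly(monthly, vocab)
    if text_featurizer is not None:
        docs = _preprocess_patient_docs(record, lexicons or load_default_lexicons())
        monthly = text_featurizer(monthly, docs)
    return fe.extract_windows(monthly, record.patient_id)


def _make_text_featurizer(config: ExperimentConfig, dev: Cohort, lexicons: LexiconSet):
    """Fit the keyword stage on the development corpus; return a featurizer
    (monthly vectors, docs-by-month) -> augmented monthly vectors."""
    method = config.keywords.method
    if method is None:
        return None
    corpus: list[TokenizedDocument] = []
    for record in dev:
        for docs in _preprocess_patient_docs(record, lexicons).values():
            corpus.extend(docs)
    if method in ("frequency", "entropy"):
        reference = (
            kw.uniform_reference()
            if config.keywords.reference == "uniform"
            else kw.late_mass_reference()
        )
        keywords = kw.select_keywords(corpus, method, config.keywords.n, reference)

        def featurize(monthly, docs_by_month):
            text = kw.keyword_count_features(docs_by_month, keywords)
            return kw.assemble_features(monthly, text, normalize_counts=True)

        featurize.keywords = keywords
        return featurize
    if method == "embedding":
        model = kw.train_embeddings(
            corpus, config.keywords.embedding, stage_seed(config.seed, "embedding")
        )

        def featurize(monthly, docs_by_month):
            text = kw.embedding_features(docs_by_month, model)
            return kw.assemble_features(monthly, text, normalize_counts=False)

        featurize.model = model
        return featurize
    raise ValueError(f"unknown keyword method {method!r}")


def _evaluate_model(
    model: LSTMClassifier, windows: list[fe.WindowSample]
) -> list[evaluation.PrognosisOutcome]:
    X = np.stack([w.vectors for w in windows])
    probs = model.predict_proba(X)
    predicted = probs.argmax(axis=1) + 1
    certainty = probs.max(axis=1)
    return [
        evaluation.make_outcome(w.patient_id, w.label, int(p), float(c))
        for w, p, c in zip(windows, predicted, certainty)
    ]


# ---------------------------------------------------------------------------
# Top-level operations


def run_experiment(config: ExperimentConfig, cohort: Cohort | None = None) -> evaluation.MetricsReport:
    """Run generate -> preprocess -> features -> train -> evaluate.

    Feature vocabulary and keyword selection are fitted on the
    development split only; the report reflects the held-out recency
    test split. Identical config (and cohort, if supplied) yields a
    byte-identical serialized report.
    """
    if cohort is None:
        gen_cfg = replace(config.generator, seed=stage_seed(config.seed, "generate"))
        logger.info("generating cohort: n=%d", gen_cfg.n_patients)
        cohort = generate_cohort(gen_cfg)
    dev, test = evaluation.split_recent(cohort, config.evaluation.test_fraction)
    logger.info("split: %d development / %d test patients", len(dev), len(test))

    vocab = fe.build_vocabulary(dev, config.category_config)
    logger.info("vocabulary: %d structured features", len(vocab))
    lexicons = load_default_lexicons()
    featurizer = _make_text_featurizer(config, dev, lexicons)

    train_windows: list[fe.WindowSample] = []
    for record in dev:
        train_windows.extend(
            _patient_windows(record, vocab, config.category_config, featurizer, lexicons)
        )
    test_windows: list[fe.WindowSample] = []
    for record in test:
        test_windows.extend(
            _patient_windows(record, vocab, config.category_config, featurizer, lexicons)
        )

    input_dim = train_windows[0].vectors.shape[1]
    model_cfg = replace(config.model, seed=stage_seed(config.seed, "model"))
    model = LSTMClassifier(model_cfg, input_dim)
    history = model.fit(
        np.stack([w.vectors for w in train_windows]),
        np.array([w.label for w in train_windows]),
    )
    logger.info("training loss: %.4f -> %.4f", history[0], history[-1])

    outcomes = _evaluate_model(model, test_windows)
    report = evaluation.build_report(outcomes)
    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
        (out / "report.txt").write_text(report.to_text() + "\n", encoding="utf-8")
        vocab.to_tsv(out / "vocabulary.tsv")
        model.save(out / "model.txt")
    return report


def _cv_score(
    dev: Cohort,
    category_config,
    model_cfg: ModelConfig,
    k: int,
    seed: int,
) -> tuple[float, float]:
    """Mean k-fold (quotient accuracy %, RMSE) for a feature/model config."""
    folds = evaluation.kfold(dev, k, seed)
    by_id = {r.patient_id: r for r in dev}
    accs, rmses = [], []
    for fold_i, (train_ids, val_ids) in enumerate(folds):
        vocab = fe.build_vocabulary(
            Cohort([by_id[i] for i in train_ids]), category_config
        )
        if len(vocab) == 0:
            return 0.0, float("inf")
        tr = [
            w
            for pid in train_ids
            for w in _patient_windows(by_id[pid], vocab, category_config)
        ]
        va = [
            w
            for pid in val_ids
            for w in _patient_windows(by_id[pid], vocab, category_config)
        ]
        model = LSTMClassifier(
            replace(model_cfg, seed=seed + fold_i), tr[0].vectors.shape[1]
        )
        model.fit(
            np.stack([w.vectors for w in tr]), np.array([w.label for w in tr])
        )
        outcomes = _evaluate_model(model, va)
        acc, _, _ = evaluation.accuracy_breakdown(outcomes)
        rmse, _ = evaluation.deviation_stats(outcomes)
        accs.append(acc)
        rmses.append(rmse)
    return float(np.mean(accs)), float(np.mean(rmses))


def stepwise_category_selection(
    dev: Cohort,
    model_cfg: ModelConfig,
    categories: tuple[str, ...] = fe.CATEGORIES,
    k: int = 10,
    seed: int = 0,
    category_config=None,
) -> list[tuple[str, float]]:
    """Greedy forward selection of feature categories.

    Starting from no categories, each round adds the category whose
    inclusion most improves cross-validated quotient accuracy; selection
    stops when no remaining category improves the score. Returns the
    addition order with the score after each addition.
    """
    if len(categories) < 2:
        raise ValueError("need at least two categories to select among")
    selected: list[str] = []
    order: list[tuple[str, float]] = []
    best_score = -np.inf
    remaining = list(categories)
    while remaining:
        scores = []
        cfg = dict(category_config or fe.DEFAULT_CATEGORY_CONFIG)
        for cat in remaining:
            active = set(selected) | {cat}
            acc, _ = _cv_score_subset(dev, cfg, active, model_cfg, k, seed)
            scores.append((acc, cat))
        scores.sort(key=lambda t: (-t[0], t[1]))
        top_acc, top_cat = scores[0]
        if top_acc <= best_score:
            break
        best_score = top_acc
        selected.append(top_cat)
        remaining.remove(top_cat)
        order.append((top_cat, top_acc))
        logger.info("stepwise: added %s (accuracy %.1f%%)", top_cat, top_acc)
    return order


def _cv_score_subset(dev, category_config, active, model_cfg, k, seed):
    """CV score using only the feature categories in ``active``."""
    folds = evaluation.kfold(dev, k, seed)
    by_id = {r.patient_id: r for r in dev}
    accs, rmses = [], []
    for fold_i, (train_ids, val_ids) in enumerate(folds):
        vocab = fe.build_vocabulary(
            Cohort([by_id[i] for i in train_ids]), category_config
        )
        entries = [(c, f) for c, f in vocab.entries if c in active]
        if not entries:
            return 0.0, float("inf")
        vocab = fe.FeatureVocabulary(entries)
        tr = [
            w
            for pid in train_ids
            for w in _patient_windows(by_id[pid], vocab, category_config)
        ]
        va = [
            w
            for pid in val_ids
            for w in _patient_windows(by_id[pid], vocab, category_config)
        ]
        model = LSTMClassifier(
            replace(model_cfg, seed=seed + fold_i), tr[0].vectors.shape[1]
        )
        model.fit(np.stack([w.vectors for w in tr]), np.array([w.label for w in tr]))
        outcomes = _evaluate_model(model, va)
        acc, _, _ = evaluation.accuracy_breakdown(outcomes)
        rmse, _ = evaluation.deviation_stats(outcomes)
        accs.append(acc)
        rmses.append(rmse)
    return float(np.mean(accs)), float(np.mean(rmses))


def grid_search(
    configs: list[ModelConfig],
    dev: Cohort,
    k: int = 10,
    category_config=None,
    seed: int = 0,
) -> tuple[ModelConfig, list[dict]]:
    """Score each model config by k-fold quotient accuracy; ties are
    broken by lower RMSE. Returns (best config, full score table)."""
    if not configs:
        raise ValueError("empty config list")
    cat_cfg = category_config or dict(fe.DEFAULT_CATEGORY_CONFIG)
    table = []
    for i, cfg in enumerate(configs):
        acc, rmse = _cv_score(dev, cat_cfg, cfg, k, seed)
        table.append({"config_index": i, "config": cfg, "accuracy_pct": acc, "rmse": rmse})
        logger.info("grid %d/%d: accuracy %.1f%%, rmse %.1f", i + 1, len(configs), acc, rmse)
    best = max(table, key=lambda row: (row["accuracy_pct"], -row["rmse"]))
    return best["config"], table
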