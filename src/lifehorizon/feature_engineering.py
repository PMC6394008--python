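"""From patient records to monthly feature vectors and windowed samples.

Each five-year history is represented by 61 monthly vectors (thirty-day
bins anchored backward from the date of death; bin 61 is the month
containing death). Events contribute frequency counts to their feature in
their bin; counts are normalized per (month, feature-category) block by
the block maximum, so all values lie in [0, 1]. A sliding window of 10
consecutive months with stride 1 yields exactly 50 training samples per
patient, labelled with the months-to-death of the window's final month
(1..50; windows touching the death month itself are excluded).

Feature construction follows the code-abstraction and filtering rules of
the structured-feature selection stage: ICPC/ICD codes may be abstracted
(drop decimals, keep the body-system letter, map to a thematic element,
or letter+element), medication strings are stripped of dosage/usage text,
lab results are kept only when flagged irregular or abnormal, and a
corpus-level frequency cut-off prunes rare features.
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path

import numpy as np

from .emr_data import Cohort, LabFlag, LabResult, PatientRecord

__all__ = [
    "AbstractionLevel",
    "CutoffMethod",
    "FeatureVocabulary",
    "MonthlyVector",
    "WindowSample",
    "CATEGORIES",
    "DEFAULT_CATEGORY_CONFIG",
    "abstract_code",
    "clean_medication",
    "filter_lab",
    "apply_cutoff",
    "build_vocabulary",
    "bin_monthly",
    "normalize_monthly",
    "extract_windows",
    "load_element_table",
]

N_MONTHS = 61
WINDOW = 10
MAX_LABEL = 50

#: The eight structured feature categories.
CATEGORIES = (
    "diagnosis_icpc",
    "reason_for_encounter_icpc",
    "icd",
    "intervention_icpc",
    "medical_history_icpc",
    "medication",
    "lab",
    "consultation_type",
)


class AbstractionLevel(Enum):
    FULL = "full"
    LETTER_NUMBER = "letter_number"
    LETTER = "letter"
    ELEMENT = "element"
    LETTER_ELEMENT = "letter_element"


class CutoffMethod(Enum):
    NONE = "none"
    ABSOLUTE_100 = "absolute_100"
    RELATIVE_1PCT = "relative_1pct"
    BOTTOM_25PCT_COVERAGE = "bottom_25pct_coverage"


#: Best-performing per-category configuration: codes without decimals for
#: diagnoses / reasons for encounter / ICD, letter+element for medical
#: history and interventions, cleaned medication names, abnormal or
#: irregular labs only, and an absolute-occurrence cut-off of 100.
DEFAULT_CATEGORY_CONFIG: dict[str, tuple[AbstractionLevel, CutoffMethod]] = {
    "diagnosis_icpc": (AbstractionLevel.LETTER_NUMBER, CutoffMethod.ABSOLUTE_100),
    "reason_for_encounter_icpc": (AbstractionLevel.LETTER_NUMBER, CutoffMethod.ABSOLUTE_100),
    "icd": (AbstractionLevel.LETTER_NUMBER, CutoffMethod.ABSOLUTE_100),
    "intervention_icpc": (AbstractionLevel.LETTER_ELEMENT, CutoffMethod.ABSOLUTE_100),
    "medical_history_icpc": (AbstractionLevel.LETTER_ELEMENT, CutoffMethod.ABSOLUTE_100),
    "medication": (AbstractionLevel.FULL, CutoffMethod.ABSOLUTE_100),
    "lab": (AbstractionLevel.FULL, CutoffMethod.ABSOLUTE_100),
    "consultation_type": (AbstractionLevel.FULL, CutoffMethod.ABSOLUTE_100),
}

_CODE_SPLIT = re.compile(r"^([A-Z])([0-9]+)(?:\.([0-9]+))?$")

_DOSE_RE = re.compile(
    r"""\b(
        \d+([.,]\d+)?\s*(mg|mcg|ug|g|ml|ie|eh|%)\b   # strength
        | \d+\s*(dd|x|maal|keer)(\s*\d+)?\b          # frequency
        | \d+dd\d*\b
        | (zo\ nodig|z\.?n\.?|per\ os|oraal|tablet(ten)?|caps(ules)?)\b
    )""",
    re.IGNORECASE | re.VERBOSE,
)


def load_element_table(path: str | Path | None = None) -> dict[int, str]:
    """Load the numeric-component -> thematic-element lookup.

    The shipped table maps inclusive numeric ranges of the ICPC process
    component to broad thematic labels and may be replaced by the user.
    """
    if path is None:
        data = resources.files("lifehorizon") / "data" / "element_table.tsv"
        text = data.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    table: dict[int, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rng, _, label = line.partition("\t")
        lo, _, hi = rng.partition("-")
        for num in range(int(lo), int(hi or lo) + 1):
            table[num] = label.strip()
    return table


def abstract_code(
    code: str, level: AbstractionLevel, element_table: dict[int, str] | None = None
) -> str:
    """Abstract an ICPC/ICD code, e.g. D84.02 -> D84 (LETTER_NUMBER) or
    D84.02 -> ``D+standard procedure`` (LETTER_ELEMENT)."""
    m = _CODE_SPLIT.match(code)
    if not m:
        raise ValueError(f"code {code!r} does not match [letter][number].[decimals]")
    letter, number = m.group(1), int(m.group(2))
    if level is AbstractionLevel.FULL:
        return code
    if level is AbstractionLevel.LETTER_NUMBER:
        return f"{letter}{m.group(2)}"
    if level is AbstractionLevel.LETTER:
        return letter
    if element_table is None or number not in element_table:
        raise KeyError(
            f"numeric component {number} of code {code!r} absent from element table"
        )
    element = element_table[number]
    if level is AbstractionLevel.ELEMENT:
        return element
    return f"{letter}+{element}"


def clean_medication(raw: str) -> str:
    """Strip dosage and usage text from a raw medication string."""
    name = _DOSE_RE.sub(" ", raw)
    name = re.sub(r"\s+", " ", name).strip()
    return name.lower()


def filter_lab(result: LabResult) -> bool:
    """Keep a lab result only when flagged irregular or abnormal."""
    return result.flag in (LabFlag.IRREGULAR, LabFlag.ABNORMAL)


def apply_cutoff(feature_counts: dict[str, float], method: CutoffMethod) -> set[str]:
    """Apply a frequency cut-off to per-category corpus counts.

    * ``NONE``: keep everything.
    * ``ABSOLUTE_100``: keep features occurring at least 100 times.
    * ``RELATIVE_1PCT``: keep features holding >= 1% of the category mass.
    * ``BOTTOM_25PCT_COVERAGE``: drop the least frequent features whose
      combined mass stays within 25% of the category total (ties broken by
      keeping the lexicographically smaller feature).
    """
    if not feature_counts:
        return set()
    if method is CutoffMethod.NONE:
        return set(feature_counts)
    if method is CutoffMethod.ABSOLUTE_100:
        return {f for f, c in feature_counts.items() if c >= 100}
    total = sum(feature_counts.values())
    if method is CutoffMethod.RELATIVE_1PCT:
        if total == 0:
            return set()
        return {f for f, c in feature_counts.items() if c / total >= 0.01}
    # BOTTOM_25PCT_COVERAGE: walk up from the rarest; a tie at equal count
    # drops the lexicographically larger feature first.
    order = sorted(feature_counts.items(), key=lambda kv: kv[0], reverse=True)
    order.sort(key=lambda kv: kv[1])  # stable: equal counts stay reverse-lexicographic
    kept = set(feature_counts)
    dropped_mass = 0.0
    for feat, count in order:
        if dropped_mass + count > 0.25 * total:
            break
        dropped_mass += count
        kept.discard(feat)
    return kept


@dataclass
class FeatureVocabulary:
    """Ordered (category, feature) entries with stable vector positions."""

    entries: list[tuple[str, str]]
    index: dict[tuple[str, str], int] = field(init=False)
    category_slices: dict[str, slice] = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate vocabulary entries")
        self.index = {entry: i for i, entry in enumerate(self.entries)}
        self.category_slices = {}
        start = 0
        for cat in CATEGORIES:
            n = sum(1 for c, _ in self.entries if c == cat)
            self.category_slices[cat] = slice(start, start + n)
            start += n

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for i, (cat, feat) in enumerate(self.entries):
                fh.write(f"{cat}\t{feat}\t{i}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureVocabulary":
        entries = []
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            cat, feat, _ = line.split("\t")
            entries.append((cat, feat))
        return cls(entries)


@dataclass
class MonthlyVector:
    month: int  # 1 = earliest, 61 = month containing death
    values: np.ndarray


@dataclass
class WindowSample:
    patient_id: str
    vectors: np.ndarray  # (WINDOW, n_features), months contiguous
    label: int  # months to death of the final month, 1..50


def _featurize_record(
    record: PatientRecord,
    per_category_config: dict[str, tuple[AbstractionLevel, CutoffMethod]],
    element_table: dict[int, str],
):
    """Yield (date, category, feature) triples for one record."""
    for cons in record.consultations:
        yield cons.date, "consultation_type", cons.consultation_type
        for ev in cons.events:
            level, _ = per_category_config[ev.category.value]
            yield cons.date, ev.category.value, abstract_code(ev.code, level, element_table)
        for lab in cons.labs:
            if filter_lab(lab):
                yield cons.date, "lab", lab.lab_code
        for med in cons.medications:
            name = clean_medication(med)
            if name:
                yield cons.date, "medication", name


def build_vocabulary(
    cohort: Cohort,
    per_category_config: dict[str, tuple[AbstractionLevel, CutoffMethod]] | None = None,
    element_table: dict[int, str] | None = None,
) -> FeatureVocabulary:
    """Abstract, count over the whole cohort, and cut off per category."""
    cfg = per_category_config or DEFAULT_CATEGORY_CONFIG
    missing = [c for c in CATEGORIES if c not in cfg]
    if missing:
        raise ValueError(f"missing category config for {missing}")
    table = element_table if element_table is not None else load_element_table()
    counts: dict[str, dict[str, float]] = {cat: {} for cat in CATEGORIES}
    for record in cohort:
        for _, cat, feat in _featurize_record(record, cfg, table):
            counts[cat][feat] = counts[cat].get(feat, 0) + 1
    entries: list[tuple[str, str]] = []
    for cat in CATEGORIES:
        _, method = cfg[cat]
        kept = apply_cutoff(counts[cat], method)
        entries.extend((cat, feat) for feat in sorted(kept))
    return FeatureVocabulary(entries)


def _month_bin(event_date: datetime.date, death_date: datetime.date) -> int | None:
    """Death-anchored 30-day bin: 61 = [death-30d, death] ... 1 = earliest.

    Events within the five calendar years but before bin 1's start fold
    into bin 1; events outside the five-year span raise.
    """
    days_before = (death_date - event_date).days
    if days_before < 0 or event_date < death_date - datetime.timedelta(days=int(365.25 * 5)):
        raise ValueError(
            f"event on {event_date} outside the five-year history ending {death_date}"
        )
    return max(1, N_MONTHS - days_before // 30)


def bin_monthly(
    record: PatientRecord,
    vocab: FeatureVocabulary,
    per_category_config: dict[str, tuple[AbstractionLevel, CutoffMethod]] | None = None,
    element_table: dict[int, str] | None = None,
) -> list[MonthlyVector]:
    """Raw frequency counts: 61 vectors over the vocabulary."""
    cfg = per_category_config or DEFAULT_CATEGORY_CONFIG
    table = element_table if element_table is not None else load_element_table()
    matrix = np.zeros((N_MONTHS, len(vocab)))
    for date, cat, feat in _featurize_record(record, cfg, table):
        pos = vocab.index.get((cat, feat))
        if pos is None:
            continue  # pruned by the cut-off
        matrix[_month_bin(date, record.death_date) - 1, pos] += 1
    return [MonthlyVector(m + 1, matrix[m]) for m in range(N_MONTHS)]


def normalize_monthly(
    vectors: list[MonthlyVector],
    vocab: FeatureVocabulary,
    per_history: bool = False,
) -> list[MonthlyVector]:
    """Divide each (month, category) block by its maximum.

    With ``per_history=True`` the divisor is instead the category maximum
    over the whole 61-month history (the alternative reading of
    month-level normalization). All-zero blocks stay zero; outputs lie in
    [0, 1] and every non-empty block contains a 1 under the default.
    """
    matrix = np.stack([v.values for v in vectors]).astype(float)
    out = matrix.copy()
    for cat, sl in vocab.category_slices.items():
        block = matrix[:, sl]
        if block.shape[1] == 0:
            continue
        if per_history:
            denom = block.max()
            if denom > 0:
                out[:, sl] = block / denom
        else:
            denom = block.max(axis=1, keepdims=True)
            nonzero = denom[:, 0] > 0
            out[nonzero, sl] = block[nonzero] / denom[nonzero]
    return [MonthlyVector(v.month, out[i]) for i, v in enumerate(vectors)]


def extract_windows(
    vectors: list[MonthlyVector], patient_id: str, window: int = WINDOW
) -> list[WindowSample]:
    """Sliding 10-month windows, stride 1; label = months to death of the
    final month. Labels outside 1..50 (the window touching death) are
    dropped, leaving one sample per label value."""
    if len(vectors) < window:
        raise ValueError(f"history of {len(vectors)} months shorter than window {window}")
    matrix = np.stack([v.values for v in vectors])
    samples = []
    for last in range(window - 1, len(vectors)):
        label = N_MONTHS - vectors[last].month
        if not (1 <= label <= MAX_LABEL):
            continue
        samples.append(
            WindowSample(
                patient_id=patient_id,
                vectors=matrix[last - window + 1 : last + 1],
                label=label,
            )
        )
    return samples
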