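"""Synthetic cohort generator for deceased-patient EMR histories.

Emulates the descriptive statistics of a Dutch general-practice cohort of
deceased patients: 52% female, mean age at death 78 years (81 for women,
76 for men), about 121 consultations per patient over the five final years
of life, free-text documents on ~75% of consultations, of which 85% are
notes and 15% letters. Clinical codes have the ICPC/ICD shape
``[letter][number].[decimals]``.

On top of that background, a configurable prognostic *signal* can be
planted: a marker code emitted a fixed number of months before death, and
terminal keywords whose emission probability ramps up as death approaches.
The planted signal is what lets the downstream feature-selection and
sequence-model stages be verified end to end without any real data.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .emr_data import (
    Cohort,
    Consultation,
    CodedEvent,
    Document,
    DocType,
    EventCategory,
    LabFlag,
    LabResult,
    PatientRecord,
    Sex,
)

__all__ = ["SignalSpec", "GeneratorConfig", "default_config", "generate_cohort"]

N_MONTHS = 61  # thirty-day bins covering the five final years of life

#: All death dates fall in a fixed 3-year window so a recency-based
#: train/test split over the cohort is meaningful.
_DEATH_WINDOW_START = datetime.date(2016, 1, 1)
_DEATH_WINDOW_DAYS = 3 * 365

_CONSULTATION_TYPES = ("visit", "phone", "administrative", "home_visit")

_LAB_CODES = ("HB", "GLUC", "CREA", "CRP", "K")

_MEDICATIONS = (
    "paracetamol 500mg 3dd",
    "metoprolol 50mg 1dd",
    "omeprazol 20mg",
    "simvastatine 40mg 1dd1",
    "furosemide 40mg zo nodig",
    "insuline",
    "morfine 10mg 2dd",
)


def _default_code_vocab() -> dict[str, list[str]]:
    """A small per-category code vocabulary of ICPC/ICD-shaped codes."""
    letters = {
        EventCategory.DIAGNOSIS_ICPC.value: "DKRLT",
        EventCategory.REASON_FOR_ENCOUNTER_ICPC.value: "ADKPS",
        EventCategory.ICD.value: "CEIJN",
        EventCategory.INTERVENTION_ICPC.value: "DKLRU",
        EventCategory.MEDICAL_HISTORY_ICPC.value: "ADHKT",
    }
    vocab: dict[str, list[str]] = {}
    for cat, lets in letters.items():
        codes = []
        for i, letter in enumerate(lets):
            for num in (11 + i, 70 + i, 84):
                codes.append(f"{letter}{num}.{i:02d}")
        vocab[cat] = codes
    return vocab


_DEFAULT_TEXT_VOCAB = (
    "patient klachten controle bloeddruk medicatie overleg huisarts gesprek "
    "pijn moe onderzoek uitslag stabiel vervolg thuis familie zorg recept "
    "verwijzing telefonisch besproken afspraak conditie eetlust gewicht "
    "benauwd slapen lopen vallen geheugen"
).split()
_DEFAULT_TEXT_VOCAB = tuple(_DEFAULT_TEXT_VOCAB)

_TERMINAL_KEYWORDS = ("palliatief", "hospice", "terminaal")


@dataclass
class SignalSpec:
    """A plantable prognostic signal (marker code + terminal keywords)."""

    marker_code: str = "Z99"
    marker_offset: int = 5  # months before death
    marker_penetrance: float = 0.0
    terminal_keywords: tuple[str, ...] = _TERMINAL_KEYWORDS
    keyword_ramp_start: int = 12  # months before death where the ramp begins
    keyword_ramp_peak: float = 0.0  # per-document emission probability at death

    def __post_init__(self) -> None:
        if not (1 <= self.marker_offset <= 50):
            raise ValueError("marker_offset must lie in 1..50")
        if self.keyword_ramp_start < 1:
            raise ValueError("keyword_ramp_start must be >= 1")


@dataclass
class GeneratorConfig:
    n_patients: int = 100
    female_fraction: float = 0.52
    death_age_mean_female: float = 81.0
    death_age_mean_male: float = 76.0
    death_age_sd: float = 8.0
    consultations_per_patient_mean: float = 121.0  # per five-year history
    document_probability: float = 0.75
    note_fraction: float = 0.85
    code_vocab: dict[str, list[str]] = field(default_factory=_default_code_vocab)
    text_vocab: tuple[str, ...] = _DEFAULT_TEXT_VOCAB
    signal: SignalSpec = field(default_factory=SignalSpec)
    #: Optional per-month multiplier on the consultation rate (length 61);
    #: default None = uniform rate across the history.
    hazard_ramp: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("female_fraction", "document_probability", "note_fraction"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.code_vocab or any(not v for v in self.code_vocab.values()):
            raise ValueError("code_vocab must be non-empty for every category")
        if not self.text_vocab:
            raise ValueError("text_vocab must be non-empty")
        if self.hazard_ramp is not None and len(self.hazard_ramp) != N_MONTHS:
            raise ValueError(f"hazard_ramp must have length {N_MONTHS}")


def default_config(seed: int) -> GeneratorConfig:
    """The calibrated defaults (cohort demographics and documentation rates)."""
    return GeneratorConfig(seed=seed)


def _sample_death_age(rng: np.random.Generator, mean: float, sd: float) -> float:
    # Normal truncated below at 18 years.
    lo = (18.0 - mean) / sd
    return float(stats.truncnorm.rvs(lo, np.inf, loc=mean, scale=sd, random_state=rng))


def _keyword_probability(spec: SignalSpec, months_to_death: int) -> float:
    """Linear ramp from 0 at ``keyword_ramp_start`` months out to the peak at death."""
    if months_to_death >= spec.keyword_ramp_start:
        return 0.0
    frac = (spec.keyword_ramp_start - months_to_death) / spec.keyword_ramp_start
    return spec.keyword_ramp_peak * frac


def _sample_document(
    rng: np.random.Generator, cfg: GeneratorConfig, months_to_death: int
) -> Document:
    doc_type = DocType.NOTE if rng.random() < cfg.note_fraction else DocType.LETTER
    n_words = 8 + int(rng.poisson(10))
    words = list(rng.choice(cfg.text_vocab, size=n_words))
    p_kw = _keyword_probability(cfg.signal, months_to_death)
    if p_kw > 0.0:
        for kw in cfg.signal.terminal_keywords:
            if rng.random() < p_kw:
                words.insert(int(rng.integers(0, len(words) + 1)), kw)
    body = " ".join(words)
    if doc_type is DocType.LETTER:
        text = f"Geachte collega,\n{body}\nMet vriendelijke groet, huisarts"
    else:
        text = body
    return Document(doc_type, text)


def _sample_consultation(
    rng: np.random.Generator,
    cfg: GeneratorConfig,
    date: datetime.date,
    months_to_death: int,
) -> Consultation:
    ctype = str(rng.choice(_CONSULTATION_TYPES))
    events = []
    for _ in range(int(rng.poisson(1.2))):
        cat = str(rng.choice(list(cfg.code_vocab)))
        code = str(rng.choice(cfg.code_vocab[cat]))
        events.append(CodedEvent(EventCategory(cat), code))
    labs = []
    for _ in range(int(rng.poisson(0.3))):
        flag = (LabFlag.NORMAL, LabFlag.IRREGULAR, LabFlag.ABNORMAL)[
            int(rng.choice(3, p=[0.7, 0.15, 0.15]))
        ]
        labs.append(LabResult(str(rng.choice(_LAB_CODES)), f"{rng.integers(1, 200)}", flag))
    medications = [str(rng.choice(_MEDICATIONS)) for _ in range(int(rng.poisson(0.5)))]
    documents = []
    if rng.random() < cfg.document_probability:
        documents.append(_sample_document(rng, cfg, months_to_death))
    return Consultation(date, ctype, events, labs, medications, documents)


def _generate_patient(rng: np.random.Generator, cfg: GeneratorConfig, idx: int) -> PatientRecord:
    sex = Sex.FEMALE if rng.random() < cfg.female_fraction else Sex.MALE
    mean_age = cfg.death_age_mean_female if sex is Sex.FEMALE else cfg.death_age_mean_male
    age = _sample_death_age(rng, mean_age, cfg.death_age_sd)
    death_date = _DEATH_WINDOW_START + datetime.timedelta(
        days=int(rng.integers(0, _DEATH_WINDOW_DAYS))
    )
    birth_date = death_date - datetime.timedelta(days=int(age * 365.25))

    base_rate = cfg.consultations_per_patient_mean / N_MONTHS
    consultations: list[Consultation] = []
    # months_to_death m covers days [30*m, 30*m+29] before death
    for m in range(N_MONTHS):
        rate = base_rate
        if cfg.hazard_ramp is not None:
            rate *= cfg.hazard_ramp[N_MONTHS - 1 - m]
        for _ in range(int(rng.poisson(rate))):
            # cap keeps the earliest bin inside five calendar years
            days_before = min(30 * m + int(rng.integers(0, 30)), 1825)
            date = death_date - datetime.timedelta(days=days_before)
            consultations.append(_sample_consultation(rng, cfg, date, m))

    sig = cfg.signal
    if sig.marker_penetrance > 0.0 and rng.random() < sig.marker_penetrance:
        m = sig.marker_offset
        days_before = 30 * m + int(rng.integers(0, 30))
        date = death_date - datetime.timedelta(days=days_before)
        marker_event = CodedEvent(EventCategory.DIAGNOSIS_ICPC, sig.marker_code)
        host = [c for c in consultations if 30 * m <= (death_date - c.date).days < 30 * (m + 1)]
        if host:
            host[0].events.append(marker_event)
        else:
            consultations.append(
                Consultation(date, "visit", events=[marker_event])
            )

    consultations.sort(key=lambda c: c.date)
    return PatientRecord(
        patient_id=f"P{idx:05d}",
        sex=sex,
        birth_date=birth_date,
        death_date=death_date,
        consultations=consultations,
    )


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a cohort; identical config + seed gives an identical cohort."""
    if config.signal.marker_penetrance > 0.0:
        for codes in config.code_vocab.values():
            if config.signal.marker_code in codes:
                raise ValueError(
                    "marker_code must not appear in the background code_vocab"
                )
    rng = np.random.default_rng(config.seed)
    patients = [_generate_patient(rng, config, i) for i in range(config.n_patients)]
    return Cohort(patients=patients)


def config_to_dict(config: GeneratorConfig) -> dict:
    """Plain-dict form of a config (for YAML/JSON round-tripping)."""
    d = asdict(config)
    d["text_vocab"] = list(config.text_vocab)
    d["signal"]["terminal_keywords"] = list(config.signal.terminal_keywords)
    if config.hazard_ramp is not None:
        d["hazard_ramp"] = list(config.hazard_ramp)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "signal" in d and isinstance(d["signal"], dict):
        sig = dict(d["signal"])
        if "terminal_keywords" in sig:
            sig["terminal_keywords"] = tuple(sig["terminal_keywords"])
        d["signal"] = SignalSpec(**sig)
    if d.get("text_vocab") is not None:
        d["text_vocab"] = tuple(d["text_vocab"])
    if d.get("hazard_ramp") is not None:
        d["hazard_ramp"] = tuple(d["hazard_ramp"])
    return GeneratorConfig(**d)
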