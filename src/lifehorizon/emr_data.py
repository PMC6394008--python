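"""Domain types and interchange I/O for death-anchored EMR cohorts.

A cohort is stored as two plain-text files:

* a CSV **manifest** with header ``patient_id,sex,birth_date,death_date``
  (ISO-8601 dates), one row per deceased patient, rows sorted by
  ``patient_id``;
* a JSON-lines **event log**, one consultation object per line with keys
  ``patient_id, date, consultation_type, events, labs, medications,
  documents`` emitted in that fixed order, so a given cohort always
  serializes to byte-identical files.

Every patient history spans the five final years of life: all consultation
dates lie in ``[death_date - 5 years, death_date]``.
"""

from __future__ import annotations

import csv
import datetime
import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path


__all__ = [
    "Sex",
    "EventCategory",
    "LabFlag",
    "DocType",
    "CodedEvent",
    "LabResult",
    "Document",
    "Consultation",
    "PatientRecord",
    "Cohort",
    "CODE_PATTERN",
    "read_cohort",
    "write_cohort",
    "validate_record",
    "CohortFormatError",
]

#: Clinical codes follow the ICPC/ICD shape ``[letter][number].[decimals]``,
#: e.g. ``D84.02`` (the letter denotes the affected body system).
CODE_PATTERN = re.compile(r"^[A-Z][0-9]+(\.[0-9]+)?$")

#: History length: five years operationalized as 61 thirty-day bins.
HISTORY_DAYS = 61 * 30


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class EventCategory(str, Enum):
    """The five coded-event categories carried on consultations."""

    DIAGNOSIS_ICPC = "diagnosis_icpc"
    REASON_FOR_ENCOUNTER_ICPC = "reason_for_encounter_icpc"
    ICD = "icd"
    INTERVENTION_ICPC = "intervention_icpc"
    MEDICAL_HISTORY_ICPC = "medical_history_icpc"


class LabFlag(str, Enum):
    NORMAL = "normal"
    IRREGULAR = "irregular"
    ABNORMAL = "abnormal"


class DocType(str, Enum):
    NOTE = "note"
    LETTER = "letter"


class CohortFormatError(ValueError):
    """Raised for malformed manifest/event-log input."""


@dataclass(frozen=True)
class CodedEvent:
    category: EventCategory
    code: str


@dataclass(frozen=True)
class LabResult:
    lab_code: str
    value: str
    flag: LabFlag


@dataclass(frozen=True)
class Document:
    doc_type: DocType
    text: str


@dataclass
class Consultation:
    date: datetime.date
    consultation_type: str
    events: list[CodedEvent] = field(default_factory=list)
    labs: list[LabResult] = field(default_factory=list)
    medications: list[str] = field(default_factory=list)
    documents: list[Document] = field(default_factory=list)


@dataclass
class PatientRecord:
    """One deceased patient: manifest entry plus dated consultations."""

    patient_id: str
    sex: Sex
    birth_date: datetime.date
    death_date: datetime.date
    consultations: list[Consultation] = field(default_factory=list)


@dataclass
class Cohort:
    patients: list[PatientRecord] = field(default_factory=list)

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)


# ---------------------------------------------------------------------------
# Reading


def _parse_date(value: str, where: str) -> datetime.date:
    try:
        return datetime.date.fromisoformat(value)
    except (TypeError, ValueError) as exc:
        raise CohortFormatError(f"malformed date {value!r} at {where}") from exc


def _parse_consultation(obj: dict, where: str) -> tuple[str, Consultation]:
    date = _parse_date(obj.get("date", ""), where)
    ctype = obj.get("consultation_type", "")
    if not ctype:
        raise CohortFormatError(f"empty consultation_type at {where}")
    events = []
    for ev in obj.get("events", []):
        code = ev["code"]
        if not CODE_PATTERN.match(code):
            raise CohortFormatError(
                f"code {code!r} does not match [letter][number].[decimals] at {where}"
            )
        events.append(CodedEvent(EventCategory(ev["category"]), code))
    labs = [
        LabResult(lb["lab_code"], lb["value"], LabFlag(lb["flag"]))
        for lb in obj.get("labs", [])
    ]
    docs = [
        Document(DocType(d["doc_type"]), d["text"]) for d in obj.get("documents", [])
    ]
    cons = Consultation(
        date=date,
        consultation_type=ctype,
        events=events,
        labs=labs,
        medications=list(obj.get("medications", [])),
        documents=docs,
    )
    return obj["patient_id"], cons


def read_cohort(manifest_path: str | Path, events_path: str | Path) -> Cohort:
    """Read a cohort from a CSV manifest and JSON-lines event log.

    Every event line must reference a manifest patient; an unknown
    ``patient_id`` raises :class:`CohortFormatError` (lines are never
    silently dropped). Consultations are sorted ascending by date.
    """
    patients: dict[str, PatientRecord] = {}
    with open(manifest_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = ["patient_id", "sex", "birth_date", "death_date"]
        if reader.fieldnames != expected:
            raise CohortFormatError(
                f"manifest header {reader.fieldnames} != {expected}"
            )
        for i, row in enumerate(reader, start=2):
            pid = row["patient_id"]
            if pid in patients:
                raise CohortFormatError(f"duplicate patient_id {pid!r} (manifest line {i})")
            patients[pid] = PatientRecord(
                patient_id=pid,
                sex=Sex(row["sex"]),
                birth_date=_parse_date(row["birth_date"], f"manifest line {i}"),
                death_date=_parse_date(row["death_date"], f"manifest line {i}"),
            )
    with open(events_path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CohortFormatError(f"events line {i}: invalid JSON") from exc
            pid, cons = _parse_consultation(obj, f"events line {i}")
            if pid not in patients:
                raise CohortFormatError(
                    f"events line {i}: patient_id {pid!r} absent from manifest"
                )
            patients[pid].consultations.append(cons)
    for rec in patients.values():
        rec.consultations.sort(key=lambda c: c.date)
    return Cohort(patients=[patients[pid] for pid in sorted(patients)])


# ---------------------------------------------------------------------------
# Writing


def _consultation_to_obj(pid: str, cons: Consultation) -> dict:
    # Key order is fixed so serialization is byte-stable.
    return {
        "patient_id": pid,
        "date": cons.date.isoformat(),
        "consultation_type": cons.consultation_type,
        "events": [
            {"category": ev.category.value, "code": ev.code} for ev in cons.events
        ],
        "labs": [
            {"lab_code": lb.lab_code, "value": lb.value, "flag": lb.flag.value}
            for lb in cons.labs
        ],
        "medications": list(cons.medications),
        "documents": [
            {"doc_type": d.doc_type.value, "text": d.text} for d in cons.documents
        ],
    }


def write_cohort(
    cohort: Cohort, manifest_path: str | Path, events_path: str | Path
) -> None:
    """Write ``cohort`` in the interchange format (byte-stable output)."""
    records = sorted(cohort.patients, key=lambda r: r.patient_id)
    with open(manifest_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["patient_id", "sex", "birth_date", "death_date"])
        for rec in records:
            writer.writerow(
                [
                    rec.patient_id,
                    rec.sex.value,
                    rec.birth_date.isoformat(),
                    rec.death_date.isoformat(),
                ]
            )
    with open(events_path, "w", encoding="utf-8") as fh:
        for rec in records:
            for cons in sorted(rec.consultations, key=lambda c: c.date):
                obj = _consultation_to_obj(rec.patient_id, cons)
                fh.write(json.dumps(obj, ensure_ascii=False, separators=(",", ":")))
                fh.write("\n")


# ---------------------------------------------------------------------------
# Validation


def validate_record(record: PatientRecord) -> list[str]:
    """Return human-readable diagnostics; empty list iff all invariants hold."""
    diags: list[str] = []
    if record.death_date <= record.birth_date:
        diags.append(
            f"{record.patient_id}: death_date {record.death_date} is not after "
            f"birth_date {record.birth_date}"
        )
    earliest = record.death_date - datetime.timedelta(days=int(365.25 * 5))
    prev: datetime.date | None = None
    for cons in record.consultations:
        if not (earliest <= cons.date <= record.death_date):
            diags.append(
                f"{record.patient_id}: consultation on {cons.date} outside the "
                f"five final years [{earliest} .. {record.death_date}]"
            )
        if prev is not None and cons.date < prev:
            diags.append(
                f"{record.patient_id}: consultations not sorted "
                f"({cons.date} after {prev})"
            )
        prev = cons.date
        if not cons.consultation_type:
            diags.append(f"{record.patient_id}: empty consultation_type on {cons.date}")
        for ev in cons.events:
            if not CODE_PATTERN.match(ev.code):
                diags.append(
                    f"{record.patient_id}: malformed code {ev.code!r} on {cons.date}"
                )
    return diags


def validate_cohort(cohort: Cohort) -> list[str]:
    diags: list[str] = []
    seen: set[str] = set()
    for rec in cohort:
        if rec.patient_id in seen:
            diags.append(f"duplicate patient_id {rec.patient_id!r}")
        seen.add(rec.patient_id)
        diags.extend(validate_record(rec))
    return diags
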