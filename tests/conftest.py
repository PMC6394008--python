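import dataclasses
import datetime

import pytest

from lifehorizon.emr_data import (
    CodedEvent,
    Cohort,
    Consultation,
    Document,
    DocType,
    EventCategory,
    LabFlag,
    LabResult,
    PatientRecord,
    Sex,
)
from lifehorizon.synthetic_cohort import SignalSpec, default_config, generate_cohort
from lifehorizon.text_pipeline import load_default_lexicons


@pytest.fixture(scope="session")
def lexicons():
    return load_default_lexicons()


@pytest.fixture
def one_patient() -> PatientRecord:
    death = datetime.date(2018, 6, 1)
    return PatientRecord(
        patient_id="P00001",
        sex=Sex.FEMALE,
        birth_date=datetime.date(1940, 3, 15),
        death_date=death,
        consultations=[
            Consultation(
                date=death - datetime.timedelta(days=35),
                consultation_type="visit",
                events=[CodedEvent(EventCategory.DIAGNOSIS_ICPC, "D84.02")],
                labs=[LabResult("HB", "7.1", LabFlag.ABNORMAL)],
                medications=["paracetamol 500mg 3dd"],
                documents=[Document(DocType.NOTE, "pt heeft pijn")],
            )
        ],
    )


@pytest.fixture
def tiny_cohort(one_patient) -> Cohort:
    other = PatientRecord(
        patient_id="P00002",
        sex=Sex.MALE,
        birth_date=datetime.date(1935, 1, 1),
        death_date=datetime.date(2018, 1, 1),
        consultations=[
            Consultation(
                date=datetime.date(2017, 12, 20),
                consultation_type="phone",
                events=[CodedEvent(EventCategory.ICD, "C18.9")],
            )
        ],
    )
    return Cohort(patients=[one_patient, other])


@pytest.fixture(scope="session")
def small_generated_cohort():
    """A 60-patient default-parameter cohort shared across tests."""
    cfg = dataclasses.replace(default_config(11), n_patients=60)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def marker_cohort():
    """120 patients with a fully penetrant marker five months before death."""
    cfg = dataclasses.replace(
        default_config(23),
        n_patients=120,
        signal=SignalSpec(marker_penetrance=1.0, marker_offset=5),
    )
    return generate_cohort(cfg)
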