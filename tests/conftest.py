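import datetime

import pytest

from telecare.corpus import (
    AdmissionRecord,
    AnnotatedCall,
    CohortDataset,
    PatientProfile,
    Utterance,
    Vocabulary,
)
from telecare.synthetic import SyntheticConfig, generate_cohort


def make_call(call_id, patient_id, date, topic_counts, scheduled=True, acts=None, attrs=None):
    """Build a call from a {topic: count} plan; optional per-topic acts/attrs."""
    utterances = []
    for topic, n in topic_counts.items():
        for _ in range(n):
            utterances.append(
                Utterance(
                    index=len(utterances),
                    speaker="patient" if len(utterances) % 2 else "nurse_telecarer",
                    topic=topic,
                    dialogue_acts=list((acts or {}).get(topic, [])),
                    attributes=list((attrs or {}).get(topic, [])),
                )
            )
    return AnnotatedCall(
        call_id=call_id, patient_id=patient_id, date=date, scheduled=scheduled, utterances=utterances
    )


def make_patient(patient_id, start="2015-03-01", end="2016-02-28"):
    return PatientProfile(
        patient_id=patient_id,
        age=60,
        intervention_start=datetime.date.fromisoformat(start),
        intervention_end=datetime.date.fromisoformat(end),
    )


@pytest.fixture(scope="session")
def vocab():
    return Vocabulary.default()


@pytest.fixture
def tiny_cohort():
    """Two patients, three calls, one admission: the smallest full dataset."""
    patients = [make_patient("A"), make_patient("B")]
    calls = [
        make_call("A-0", "A", datetime.date(2015, 3, 10), {"lifestyle_management": 2, "vitals": 8}),
        make_call("A-1", "A", datetime.date(2015, 4, 2), {"symptom_checking": 5}),
        make_call("B-0", "B", datetime.date(2015, 3, 15), {"social_chatting": 3, "lifestyle_management": 1}),
    ]
    admissions = [
        AdmissionRecord(
            patient_id="A",
            admit_date=datetime.date(2015, 6, 1),
            discharge_date=datetime.date(2015, 6, 6),
        )
    ]
    return CohortDataset(patients=patients, calls=calls, admissions=admissions)


@pytest.fixture(scope="session")
def small_synthetic():
    """A 12-patient generated cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(seed=7, n_patients=12))
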