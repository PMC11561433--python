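"""Domain model for annotated telecare call corpora.

A cohort dataset bundles four record streams: patient profiles, annotated
calls (ordered utterances, each carrying a speaker, exactly one topic, and
optional dialogue acts and symptom/lifestyle/vitals attributes), dated
inpatient admissions, and optional expert concern evaluations.  All analyses
downstream operate on these label counts; utterance text is optional and
never consulted.
"""

from __future__ import annotations

import datetime
from collections import Counter
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator


class CorpusError(Exception):
    """Base class for corpus validation failures."""


class ParseError(CorpusError):
    """A record could not be parsed from its interchange format."""


class VocabularyError(CorpusError):
    """A label is not in the declared annotation vocabulary."""


class ReferentialError(CorpusError):
    """A call, admission or concern references an unknown patient or call."""


# ---------------------------------------------------------------------------
# Vocabulary

class Vocabulary:
    """Annotation vocabulary: topics, speakers, dialogue acts and attributes.

    The default vocabulary (shipped as ``data/vocabulary.yaml``) lists 13
    conversation topics, 4 speaker roles, 18 dialogue acts grouped into 7
    reporting categories, and the symptom/lifestyle/vitals attribute
    inventories.  Custom vocabularies may extend or replace it via
    :meth:`from_yaml`.
    """

    def __init__(self, topics, speakers, dialogue_act_categories, attribute_groups):
        self.topics = list(topics)
        self.speakers = list(speakers)
        # mapping: category -> list of act labels
        self.dialogue_act_categories = {k: list(v) for k, v in dialogue_act_categories.items()}
        self.attribute_groups = {k: list(v) for k, v in attribute_groups.items()}
        self._topic_set = set(self.topics)
        self._speaker_set = set(self.speakers)
        self._act_set = {a for acts in self.dialogue_act_categories.values() for a in acts}
        self._attr_set = {a for attrs in self.attribute_groups.values() for a in attrs}
        self._act_to_category = {
            a: cat for cat, acts in self.dialogue_act_categories.items() for a in acts
        }

    @classmethod
    def from_mapping(cls, data: dict) -> "Vocabulary":
        try:
            return cls(
                topics=data["topics"],
                speakers=data["speakers"],
                dialogue_act_categories=data["dialogue_acts"],
                attribute_groups=data["attributes"],
            )
        except KeyError as exc:  # pragma: no cover - defensive
            raise ParseError(f"vocabulary config missing section {exc}") from exc

    @classmethod
    def from_yaml(cls, path) -> "Vocabulary":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "Vocabulary":
        text = resources.files("telecare").joinpath("data/vocabulary.yaml").read_text()
        return cls.from_mapping(yaml.safe_load(text))

    @property
    def dialogue_acts(self) -> list:
        return sorted(self._act_set)

    @property
    def attributes(self) -> list:
        return sorted(self._attr_set)

    def act_category(self, act: str) -> str:
        return self._act_to_category[act]

    # -- validation --------------------------------------------------------

    def validate_utterance(self, utt: "Utterance", where: str = "") -> None:
        ctx = f" ({where})" if where else ""
        if utt.topic not in self._topic_set:
            raise VocabularyError(f"unknown topic label {utt.topic!r}{ctx}")
        if utt.speaker not in self._speaker_set:
            raise VocabularyError(f"unknown speaker label {utt.speaker!r}{ctx}")
        for act in utt.dialogue_acts:
            if act not in self._act_set:
                raise VocabularyError(f"unknown dialogue act {act!r}{ctx}")
        for attr in utt.attributes:
            if attr not in self._attr_set:
                raise VocabularyError(f"unknown attribute {attr!r}{ctx}")

    def validate_call(self, call: "AnnotatedCall") -> None:
        for utt in call.utterances:
            self.validate_utterance(utt, where=f"call {call.call_id}, utterance {utt.index}")


# ---------------------------------------------------------------------------
# Record types

class Utterance(BaseModel):
    """A single annotated unit of speech within a call.

    Each utterance carries exactly one topic (the predominant subject of the
    unit); dialogue acts and attributes are optional and may hold several
    values.
    """

    index: int = Field(ge=0)
    speaker: str
    topic: str
    dialogue_acts: list[str] = Field(default_factory=list)
    attributes: list[str] = Field(default_factory=list)
    text: Optional[str] = None

    @field_validator("topic")
    @classmethod
    def _single_topic(cls, v):
        if not isinstance(v, str):
            raise ValueError("topic must be a single label")
        return v


class AnnotatedCall(BaseModel):
    """One telecare call: an ordered, contiguously indexed utterance list."""

    call_id: str
    patient_id: str
    date: datetime.date
    scheduled: bool = True
    utterances: list[Utterance] = Field(min_length=1)

    @model_validator(mode="after")
    def _contiguous_indices(self):
        for i, utt in enumerate(self.utterances):
            if utt.index != i:
                raise ValueError(
                    f"call {self.call_id}: utterance indices must be contiguous from 0 "
                    f"(position {i} has index {utt.index})"
                )
        return self

    @property
    def n_utterances(self) -> int:
        return len(self.utterances)

    def topic_counts(self) -> Counter:
        return Counter(u.topic for u in self.utterances)


class PatientProfile(BaseModel):
    """Demographics, comorbidity flags and the patient-specific intervention window."""

    patient_id: str
    age: float = Field(ge=0)
    gender: str = "unknown"
    ethnicity: str = "unknown"
    has_hf: bool = True
    has_t2dm: bool = False
    intervention_start: datetime.date
    intervention_end: datetime.date

    @model_validator(mode="after")
    def _ordered_window(self):
        if self.intervention_start > self.intervention_end:
            raise ValueError(
                f"patient {self.patient_id}: intervention_start after intervention_end"
            )
        return self


class AdmissionRecord(BaseModel):
    """A dated inpatient stay; length of stay is whole bed days."""

    patient_id: str
    admit_date: datetime.date
    discharge_date: datetime.date
    cause: str = "all_cause"
    elective: bool = False

    @field_validator("cause")
    @classmethod
    def _known_cause(cls, v):
        if v not in {"all_cause", "cvd_related", "hf_related"}:
            raise ValueError(f"unknown admission cause {v!r}")
        return v

    @model_validator(mode="after")
    def _ordered_stay(self):
        if self.discharge_date < self.admit_date:
            raise ValueError(f"patient {self.patient_id}: discharge before admission")
        return self

    @property
    def length_of_stay(self) -> int:
        """Bed days: discharge minus admission; a same-day stay counts 0."""
        return (self.discharge_date - self.admit_date).days


CONCERN_AREAS = (
    "hf_symptoms",
    "influenza_symptoms",
    "gastrointestinal_symptoms",
    "vitals",
    "comorbidities",
    "lifestyle_management",
    "medication_management",
    "others",
)

# ordered from least to most escalated
FOLLOW_UP_LEVELS = (
    "business_as_usual",
    "case_review",
    "call_patient",
    "advise_gp_polyclinic",
)


class ConcernRecord(BaseModel):
    """An expert reviewer's judgment on one call.

    ``concern_areas`` may be empty (the call raised no concern) or hold
    several overlapping areas.  ``follow_up`` is absent for unflagged calls:
    the follow-up inventory applies to flagged concerns only.
    """

    call_id: str
    rater_id: str
    concern_areas: set[str] = Field(default_factory=set)
    follow_up: Optional[str] = None
    remarks: Optional[str] = None

    @field_validator("concern_areas")
    @classmethod
    def _known_areas(cls, v):
        unknown = set(v) - set(CONCERN_AREAS)
        if unknown:
            raise ValueError(f"unknown concern area(s) {sorted(unknown)}")
        return v

    @field_validator("follow_up")
    @classmethod
    def _known_level(cls, v):
        if v is not None and v not in FOLLOW_UP_LEVELS:
            raise ValueError(f"unknown follow-up level {v!r}")
        return v

    @property
    def flagged(self) -> bool:
        return len(self.concern_areas) > 0


class CohortDataset(BaseModel):
    """The full analysis substrate: patients, calls, admissions, concerns."""

    patients: list[PatientProfile]
    calls: list[AnnotatedCall] = Field(default_factory=list)
    admissions: list[AdmissionRecord] = Field(default_factory=list)
    concerns: Optional[list[ConcernRecord]] = None

    @model_validator(mode="after")
    def _referential_integrity(self):
        known = {p.patient_id for p in self.patients}
        for call in self.calls:
            if call.patient_id not in known:
                raise ValueError(f"call {call.call_id} references unknown patient {call.patient_id}")
        for adm in self.admissions:
            if adm.patient_id not in known:
                raise ValueError(f"admission references unknown patient {adm.patient_id}")
        return self

    def patient(self, patient_id: str) -> PatientProfile:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise ReferentialError(f"unknown patient {patient_id}")

    def calls_for(self, patient_id: str) -> list[AnnotatedCall]:
        return [c for c in self.calls if c.patient_id == patient_id]

    def admissions_for(self, patient_id: str) -> list[AdmissionRecord]:
        return [a for a in self.admissions if a.patient_id == patient_id]


# ---------------------------------------------------------------------------
# Operations

def merge_same_day_calls(calls: list[AnnotatedCall]) -> list[AnnotatedCall]:
    """Merge calls sharing (patient, date) into one call, sorted by date.

    Multiple same-day calls (a dropped connection, separate caregiver and
    patient conversations) count as one conversation: their utterances are
    concatenated in input order and reindexed contiguously.  Idempotent, and
    preserves the total utterance count.
    """
    by_key: dict[tuple, list[AnnotatedCall]] = {}
    for call in calls:
        by_key.setdefault((call.patient_id, call.date), []).append(call)

    merged: list[AnnotatedCall] = []
    for (patient_id, date), group in by_key.items():
        if len(group) == 1:
            merged.append(group[0])
            continue
        utterances = []
        for call in group:
            for utt in call.utterances:
                utterances.append(utt.model_copy(update={"index": len(utterances)}))
        merged.append(
            AnnotatedCall(
                call_id=group[0].call_id,
                patient_id=patient_id,
                date=date,
                scheduled=any(c.scheduled for c in group),
                utterances=utterances,
            )
        )
    merged.sort(key=lambda c: (c.patient_id, c.date, c.call_id))
    return merged


def corpus_summary(dataset: CohortDataset) -> dict:
    """Cohort-level descriptors: call counts, utterance distribution, topic shares.

    Raises :class:`CorpusError` on an empty dataset (no calls) so callers never
    mistake an empty corpus for a degenerate one.
    """
    if not dataset.calls:
        raise CorpusError("empty dataset: no calls to summarize")

    import numpy as np

    sizes = np.array([c.n_utterances for c in dataset.calls])
    topic_totals: Counter = Counter()
    for call in dataset.calls:
        topic_totals.update(call.topic_counts())
    total = int(sizes.sum())
    return {
        "n_patients": len({c.patient_id for c in dataset.calls}),
        "n_calls": len(dataset.calls),
        "n_utterances": total,
        "utterances_per_call": {
            "min": int(sizes.min()),
            "median": float(np.median(sizes)),
            "max": int(sizes.max()),
        },
        "topic_shares": {t: n / total for t, n in sorted(topic_totals.items())},
    }
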