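"""Readers and writers for the corpus interchange formats.

Calls travel as JSON Lines (one call object per line); patients, admissions
and concern records as headered CSV with ISO-8601 dates.  Loading validates
every record against the annotation vocabulary and checks referential
integrity across streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import ValidationError

from .corpus import (
    AdmissionRecord,
    AnnotatedCall,
    CohortDataset,
    ConcernRecord,
    ParseError,
    PatientProfile,
    ReferentialError,
    Vocabulary,
)


@dataclass
class CorpusPaths:
    """File locations for one cohort's interchange files."""

    calls: Optional[Path] = None
    patients: Optional[Path] = None
    admissions: Optional[Path] = None
    concerns: Optional[Path] = None
    vocabulary: Optional[Path] = None


# ---------------------------------------------------------------------------
# Calls: JSON Lines

def load_calls_jsonl(path) -> list[AnnotatedCall]:
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}:{lineno}: invalid JSON ({exc.msg})") from exc
            try:
                calls.append(AnnotatedCall.model_validate(obj))
            except ValidationError as exc:
                raise ParseError(f"{path}:{lineno}: {exc.errors()[0]['msg']}") from exc
    return calls


def write_calls_jsonl(calls: list[AnnotatedCall], path) -> None:
    with open(path, "w") as fh:
        for call in calls:
            fh.write(json.dumps(call.model_dump(mode="json"), sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Patients / admissions / concerns: CSV

def load_patients_csv(path) -> list[PatientProfile]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    try:
        return [PatientProfile.model_validate(row) for row in frame.to_dict("records")]
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc.errors()[0]['msg']}") from exc


def write_patients_csv(patients: list[PatientProfile], path) -> None:
    pd.DataFrame([p.model_dump(mode="json") for p in patients]).to_csv(path, index=False)


def load_admissions_csv(path) -> list[AdmissionRecord]:
    frame = pd.read_csv(path, dtype={"patient_id": str})
    try:
        return [AdmissionRecord.model_validate(row) for row in frame.to_dict("records")]
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc.errors()[0]['msg']}") from exc


def write_admissions_csv(admissions: list[AdmissionRecord], path) -> None:
    pd.DataFrame([a.model_dump(mode="json") for a in admissions]).to_csv(path, index=False)


def load_concerns_csv(path) -> list[ConcernRecord]:
    """Concern records: ``concern_areas`` is a semicolon-joined label list."""
    frame = pd.read_csv(path, dtype={"call_id": str, "rater_id": str})
    records = []
    for row in frame.to_dict("records"):
        areas = row.get("concern_areas")
        if isinstance(areas, str) and areas:
            row["concern_areas"] = set(areas.split(";"))
        else:
            row["concern_areas"] = set()
        follow_up = row.get("follow_up")
        if not isinstance(follow_up, str) or not follow_up:
            row["follow_up"] = None
        remarks = row.get("remarks")
        if not isinstance(remarks, str):
            row["remarks"] = None
        try:
            records.append(ConcernRecord.model_validate(row))
        except ValidationError as exc:
            raise ParseError(f"{path}: {exc.errors()[0]['msg']}") from exc
    return records


def write_concerns_csv(concerns: list[ConcernRecord], path) -> None:
    rows = [
        {
            "call_id": c.call_id,
            "rater_id": c.rater_id,
            "concern_areas": ";".join(sorted(c.concern_areas)),
            "follow_up": c.follow_up or "",
            "remarks": c.remarks or "",
        }
        for c in concerns
    ]
    pd.DataFrame(rows, columns=["call_id", "rater_id", "concern_areas", "follow_up", "remarks"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# Cohort-level load / write

def load_corpus(paths: CorpusPaths, vocabulary: Optional[Vocabulary] = None) -> CohortDataset:
    """Load and validate a full cohort from its interchange files.

    Every utterance label is checked against the vocabulary (the shipped
    default unless ``paths.vocabulary`` or ``vocabulary`` overrides it), and
    every call/admission must reference a known patient.
    """
    if vocabulary is None:
        vocabulary = (
            Vocabulary.from_yaml(paths.vocabulary) if paths.vocabulary else Vocabulary.default()
        )

    patients = load_patients_csv(paths.patients) if paths.patients else []
    calls = load_calls_jsonl(paths.calls) if paths.calls else []
    admissions = load_admissions_csv(paths.admissions) if paths.admissions else []
    concerns = load_concerns_csv(paths.concerns) if paths.concerns else None

    for call in calls:
        vocabulary.validate_call(call)

    try:
        return CohortDataset(
            patients=patients, calls=calls, admissions=admissions, concerns=concerns
        )
    except ValidationError as exc:
        raise ReferentialError(exc.errors()[0]["msg"]) from exc


def write_corpus(dataset: CohortDataset, out_dir, prefix: str = "cohort") -> CorpusPaths:
    """Write a cohort's interchange file set; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = CorpusPaths(
        calls=out / f"{prefix}_calls.jsonl",
        patients=out / f"{prefix}_patients.csv",
        admissions=out / f"{prefix}_admissions.csv",
    )
    write_calls_jsonl(dataset.calls, paths.calls)
    write_patients_csv(dataset.patients, paths.patients)
    write_admissions_csv(dataset.admissions, paths.admissions)
    if dataset.concerns is not None:
        paths.concerns = out / f"{prefix}_concerns.csv"
        write_concerns_csv(dataset.concerns, paths.concerns)
    return paths
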