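"""Synthetic telecare cohorts with ground-truth focus events.

The generator emulates the statistical structure the analysis assumes: each
patient has 11-15 calls over roughly a year, call sizes are log-uniform
between 11 and 1289 utterances, the lifestyle-management topic occupies a
low (~2%) baseline share of utterances, and 0-4 planted *focus events* per
patient lift that share by an additive boost for 1-2 consecutive calls.
Dialogue-act counts per call differ by planted group (negative-binomial
around means 17.5 vs 10.1), and each patient's average length of stay is
coupled to their planted focus-call count through a Gaussian copula so that
the rank correlation targets a configurable value (default -0.3).

Every generated dataset passes full corpus validation, and the planted
event indicator is returned as ground truth for recovery testing.  No
utterance text is generated: analyses consume labels and counts only.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.stats import norm

from .corpus import (
    AdmissionRecord,
    AnnotatedCall,
    CohortDataset,
    ConcernRecord,
    CONCERN_AREAS,
    FOLLOW_UP_LEVELS,
    PatientProfile,
    Utterance,
    Vocabulary,
)
from .focus import FOCUSED, FocusLabel

# weights over the non-lifestyle topics in the default vocabulary (relative
# conversational prevalence; renormalised to the non-lifestyle share)
_BASE_TOPIC_WEIGHTS = {
    "introduction": 3.0,
    "identification": 2.0,
    "appointments": 5.0,
    "telemonitoring": 10.0,
    "general_education": 8.0,
    "customized_coaching": 6.0,
    "related_medical_experience": 8.0,
    "symptom_checking": 18.0,
    "vitals": 12.0,
    "medication_management": 10.0,
    "social_chatting": 12.0,
    "others": 6.0,
}

# dialogue-act category mix within lifestyle exchanges (coaching-style calls
# are dominated by information exchange)
_ACT_CATEGORY_WEIGHTS = {
    "exchanging_information": 0.62,
    "understanding_information": 0.17,
    "performing_action": 0.045,
    "evaluation_of_health_condition": 0.025,
    "social_emotional": 0.035,
    "incomplete_dialogue_act": 0.075,
    "others": 0.03,
}

# concern-area marginal weights and follow-up level weights for flagged calls
_CONCERN_AREA_WEIGHTS = (12, 6, 3, 12, 7, 4, 3, 1)
_FOLLOW_UP_WEIGHTS = (5, 26, 7, 10)


class SyntheticConfigError(ValueError):
    """The requested generator configuration is infeasible."""


_UTTERANCE_FIELDS = frozenset(
    {"index", "speaker", "topic", "dialogue_acts", "attributes", "text"}
)


def _fast_utterance(index: int, speaker: str, topic: str) -> Utterance:
    """Build a trusted Utterance without validation overhead.

    The generator controls every value, so this skips pydantic validation
    (the dataset is still fully re-validatable through the loaders).
    """
    utt = object.__new__(Utterance)
    object.__setattr__(
        utt,
        "__dict__",
        {
            "index": index,
            "speaker": speaker,
            "topic": topic,
            "dialogue_acts": [],
            "attributes": [],
            "text": None,
        },
    )
    object.__setattr__(utt, "__pydantic_fields_set__", set(_UTTERANCE_FIELDS))
    object.__setattr__(utt, "__pydantic_extra__", None)
    object.__setattr__(utt, "__pydantic_private__", None)
    return utt


class SyntheticConfig(BaseModel):
    """Cohort-generation parameters; defaults define the study conditions."""

    n_patients: int = Field(default=50, ge=1)
    calls_per_patient: tuple[int, int] = (11, 15)
    utterances_per_call: tuple[int, int] = (11, 1289)
    baseline_topic_share: float = Field(default=0.02, ge=0, le=1)
    focus_events_per_patient: tuple[int, int] = (0, 4)
    focus_ratio_boost: float = Field(default=0.10, ge=0, le=1)
    event_duration: tuple[int, int] = (1, 2)
    dialogue_act_means: tuple[float, float] = (17.5, 10.1)  # (focused, not focused)
    dialogue_act_sds: tuple[float, float] = (12.4, 7.7)
    utilization_coupling: float = Field(default=-0.3, ge=-1, le=1)
    admission_rate: float = Field(default=3.4, ge=0)
    los_mean: float = Field(default=6.5, ge=0)
    los_sd: float = Field(default=2.4, ge=0)
    stay_noise_sd: float = Field(default=1.0, ge=0)  # per-stay spread around the patient's LOS level
    concern_flag_rate: float = Field(default=0.242, ge=0, le=1)
    concern_overlap_rate: float = Field(default=0.2, ge=0, le=1)
    n_eval_calls: int = Field(default=120, ge=0)
    topic: str = "lifestyle_management"
    seed: int = 0

    @model_validator(mode="after")
    def _feasible(self):
        for name in ("calls_per_patient", "utterances_per_call", "focus_events_per_patient", "event_duration"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise SyntheticConfigError(f"{name} range ({lo}, {hi}) is empty or negative")
        if self.baseline_topic_share + self.focus_ratio_boost > 1:
            raise SyntheticConfigError("baseline share plus boost exceeds 1")
        if self.utterances_per_call[0] < 1:
            raise SyntheticConfigError("calls need at least 1 utterance")
        return self


@dataclass
class GroundTruth:
    """Planted focus-event indicators keyed by call id."""

    planted: dict[str, bool]
    planted_counts: dict[str, int]  # per patient

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.planted.items()), columns=["call_id", "is_planted_focus"]
        )


def inject_focus_events(
    trajectory: list[float], events: list[tuple[int, int]], boost: float
) -> list[float]:
    """Add ``boost`` to the expected topic share at event calls, capped at 1.

    ``events`` is a list of (start, duration) pairs in call-order units;
    overlapping events merge (a call is boosted once).  Non-event calls are
    returned unchanged.
    """
    n = len(trajectory)
    hit: set[int] = set()
    for start, duration in events:
        if start < 0 or start >= n:
            raise ValueError(f"event start {start} outside trajectory of length {n}")
        hit.update(range(start, min(start + duration, n)))
    return [min(1.0, s + boost) if i in hit else s for i, s in enumerate(trajectory)]


def _event_call_indices(rng, n_calls: int, config: SyntheticConfig) -> set[int]:
    lo, hi = config.focus_events_per_patient
    k = int(rng.integers(lo, hi + 1))
    k = min(k, n_calls)
    if k == 0:
        return set()
    starts = rng.choice(n_calls, size=k, replace=False)
    d_lo, d_hi = config.event_duration
    hit: set[int] = set()
    for start in starts:
        duration = int(rng.integers(d_lo, d_hi + 1))
        hit.update(range(int(start), min(int(start) + duration, n_calls)))
    return hit


def _call_topic_mixture(patient_mix: np.ndarray, topics: list[str], topic_idx: int, boosted: bool, boost: float) -> np.ndarray:
    mix = patient_mix.copy()
    if boosted:
        new_share = min(1.0, mix[topic_idx] + boost)
        other = 1.0 - mix[topic_idx]
        scale = (1.0 - new_share) / other if other > 0 else 0.0
        mix *= scale
        mix[topic_idx] = new_share
    return mix / mix.sum()


def _sample_act_counts(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Negative-binomial draws via the gamma-Poisson mixture, matching (mean, sd)."""
    var = sd**2
    if var <= mean:  # Poisson or underdispersed request: fall back to Poisson
        return rng.poisson(mean, size=size)
    shape = mean**2 / (var - mean)
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def generate_cohort(config: SyntheticConfig | None = None) -> tuple[CohortDataset, GroundTruth]:
    """Draw a full cohort (patients, calls, admissions) plus ground truth.

    Fully reproducible from ``config.seed``.  Admissions are coupled to the
    realised planted-focus-call counts through a Gaussian copula: patients
    are rank-transformed to normal scores (ties broken at random) and their
    average-LOS level is drawn from a correlated normal, with the copula
    correlation set so the *rank* correlation targets
    ``config.utilization_coupling``.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    vocab = Vocabulary.default()
    topics = vocab.topics
    if config.topic not in topics:
        raise SyntheticConfigError(f"target topic {config.topic!r} not in vocabulary")
    topic_idx = topics.index(config.topic)

    base_mix = np.empty(len(topics))
    base_mix[topic_idx] = config.baseline_topic_share
    other_total = 1.0 - config.baseline_topic_share
    weight_sum = sum(_BASE_TOPIC_WEIGHTS.get(t, 1.0) for t in topics if t != config.topic)
    for i, t in enumerate(topics):
        if i != topic_idx:
            base_mix[i] = other_total * _BASE_TOPIC_WEIGHTS.get(t, 1.0) / weight_sum

    speakers = np.array(["nurse_telecarer", "patient", "caregiver"])
    speaker_p = np.array([0.50, 0.45, 0.05])
    symptom_topic_idx = topics.index("symptom_checking")
    act_categories = list(_ACT_CATEGORY_WEIGHTS)
    act_cat_p = np.array(list(_ACT_CATEGORY_WEIGHTS.values()))
    act_cat_p = act_cat_p / act_cat_p.sum()
    symptoms = vocab.attribute_groups["symptoms"]
    symptom_attrs = vocab.attribute_groups["symptom_attributes"]

    patients: list[PatientProfile] = []
    calls: list[AnnotatedCall] = []
    planted: dict[str, bool] = {}
    planted_counts: dict[str, int] = {}
    log_lo, log_hi = math.log(config.utterances_per_call[0]), math.log(config.utterances_per_call[1])

    for p in range(config.n_patients):
        pid = f"P{p:03d}"
        start = datetime.date(2015, 1, 1) + datetime.timedelta(days=int(rng.integers(0, 365)))
        duration = int(rng.integers(300, 430))
        end = start + datetime.timedelta(days=duration)
        patients.append(
            PatientProfile(
                patient_id=pid,
                age=float(np.clip(rng.normal(59, 14.3), 21, 95).round(0)),
                gender=str(rng.choice(["male", "female"], p=[0.74, 0.26])),
                ethnicity=str(rng.choice(["chinese", "malay", "indian", "others"], p=[0.58, 0.16, 0.14, 0.12])),
                has_hf=True,
                has_t2dm=bool(rng.random() < 0.5),
                intervention_start=start,
                intervention_end=end,
            )
        )

        c_lo, c_hi = config.calls_per_patient
        n_calls = int(rng.integers(c_lo, c_hi + 1))
        call_days = np.sort(rng.choice(duration + 1, size=n_calls, replace=False))
        patient_mix = rng.dirichlet(base_mix * 300.0)
        # keep the target-topic share exactly at its configured baseline scale
        patient_mix[topic_idx] = max(patient_mix[topic_idx], 1e-4)
        patient_mix /= patient_mix.sum()
        event_idx = _event_call_indices(rng, n_calls, config)
        planted_counts[pid] = len(event_idx)

        for j, day in enumerate(call_days):
            call_id = f"{pid}-C{j:02d}"
            boosted = j in event_idx
            planted[call_id] = boosted
            mix = _call_topic_mixture(patient_mix, topics, topic_idx, boosted, config.focus_ratio_boost)
            n_utt = int(round(math.exp(rng.uniform(log_lo, log_hi))))
            n_utt = int(np.clip(n_utt, config.utterances_per_call[0], config.utterances_per_call[1]))
            counts = rng.multinomial(n_utt, mix)
            topic_labels = np.repeat(np.arange(len(topics)), counts)
            rng.shuffle(topic_labels)
            speaker_labels = speakers[rng.choice(len(speakers), size=n_utt, p=speaker_p)].tolist()

            utterances = [
                _fast_utterance(idx, speaker_labels[idx], topics[topic_labels[idx]])
                for idx in range(n_utt)
            ]
            lifestyle_positions = np.flatnonzero(topic_labels == topic_idx).tolist()
            symptom_positions = np.flatnonzero(topic_labels == symptom_topic_idx)
            if symptom_positions.size:
                tagged = symptom_positions[rng.random(symptom_positions.size) < 0.15]
                for pos in tagged:
                    attrs = utterances[int(pos)].attributes
                    attrs.append(symptoms[int(rng.integers(len(symptoms)))])
                    if rng.random() < 0.5:
                        attrs.append(symptom_attrs[int(rng.integers(len(symptom_attrs)))])

            if lifestyle_positions:
                mean, sd = (
                    (config.dialogue_act_means[0], config.dialogue_act_sds[0])
                    if boosted
                    else (config.dialogue_act_means[1], config.dialogue_act_sds[1])
                )
                n_acts = int(_sample_act_counts(rng, mean, sd, 1)[0])
                for _ in range(n_acts):
                    pos = lifestyle_positions[int(rng.integers(len(lifestyle_positions)))]
                    category = act_categories[int(rng.choice(len(act_categories), p=act_cat_p))]
                    act = str(rng.choice(vocab.dialogue_act_categories[category]))
                    utterances[pos].dialogue_acts.append(act)

            calls.append(
                AnnotatedCall(
                    call_id=call_id,
                    patient_id=pid,
                    date=start + datetime.timedelta(days=int(day)),
                    scheduled=bool(rng.random() < 0.85),
                    utterances=utterances,
                )
            )

    admissions = _generate_admissions(rng, patients, planted_counts, config)
    dataset = CohortDataset(patients=patients, calls=calls, admissions=admissions)
    return dataset, GroundTruth(planted=planted, planted_counts=planted_counts)


def _generate_admissions(
    rng, patients: list[PatientProfile], planted_counts: dict[str, int], config: SyntheticConfig
) -> list[AdmissionRecord]:
    n = len(patients)
    counts = np.array([planted_counts[p.patient_id] for p in patients], dtype=float)
    # normal scores of the planted-focus-call counts, ties broken at random
    order = np.lexsort((rng.random(n), counts))
    positions = np.empty(n, dtype=float)
    positions[order] = np.arange(n)
    z1 = norm.ppf((positions + 0.5) / n)
    # copula correlation giving the requested Spearman rho for bivariate normals
    r = 2.0 * math.sin(math.pi * config.utilization_coupling / 6.0)
    z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r**2)) * rng.standard_normal(n)
    los_level = np.maximum(0.5, config.los_mean + config.los_sd * z2)

    admissions: list[AdmissionRecord] = []
    for i, profile in enumerate(patients):
        window_lo = profile.intervention_start - datetime.timedelta(days=183)
        window_days = (profile.intervention_end - profile.intervention_start).days + 366
        n_adm = int(rng.poisson(config.admission_rate))
        for _ in range(n_adm):
            admit = window_lo + datetime.timedelta(days=int(rng.integers(0, window_days + 1)))
            los = max(0, int(round(rng.normal(los_level[i], config.stay_noise_sd))))
            admissions.append(
                AdmissionRecord(
                    patient_id=profile.patient_id,
                    admit_date=admit,
                    discharge_date=admit + datetime.timedelta(days=los),
                    cause="all_cause",
                    elective=False,
                )
            )
        if rng.random() < 0.15:  # occasional elective day procedure, excluded downstream
            admit = window_lo + datetime.timedelta(days=int(rng.integers(0, window_days + 1)))
            admissions.append(
                AdmissionRecord(
                    patient_id=profile.patient_id,
                    admit_date=admit,
                    discharge_date=admit + datetime.timedelta(days=int(rng.integers(0, 2))),
                    cause="all_cause",
                    elective=True,
                )
            )
    return admissions


def generate_expert_evaluations(
    dataset: CohortDataset,
    labels: dict[str, FocusLabel],
    config: SyntheticConfig | None = None,
) -> list[ConcernRecord]:
    """Draw concern evaluations for a sample of labelled calls.

    Calls come from patients who have at least one focused call (mirroring a
    purposively sampled evaluation cohort); each sampled call is flagged
    with probability ``concern_flag_rate``, flagged calls draw one concern
    area from the configured marginal weights (plus a second overlapping
    area with probability ``concern_overlap_rate``) and a follow-up level;
    unflagged calls carry no areas and no follow-up level.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed + 104729)

    focused_patients = {
        cid.rsplit("-", 1)[0] for cid, lab in labels.items() if lab.group == FOCUSED
    }
    eligible = [c for c in dataset.calls if c.call_id in labels and c.patient_id in focused_patients]
    if not eligible:
        eligible = [c for c in dataset.calls if c.call_id in labels]
    eligible = sorted(eligible, key=lambda c: c.call_id)
    n_take = min(config.n_eval_calls, len(eligible))
    chosen = rng.choice(len(eligible), size=n_take, replace=False) if n_take else []

    area_p = np.array(_CONCERN_AREA_WEIGHTS, dtype=float)
    area_p /= area_p.sum()
    level_p = np.array(_FOLLOW_UP_WEIGHTS, dtype=float)
    level_p /= level_p.sum()

    records = []
    for k in sorted(int(i) for i in np.atleast_1d(chosen)):
        call = eligible[k]
        rater = "R1" if sum(call.patient_id.encode()) % 2 == 0 else "R2"
        if rng.random() < config.concern_flag_rate:
            areas = {str(CONCERN_AREAS[int(rng.choice(len(CONCERN_AREAS), p=area_p))])}
            if rng.random() < config.concern_overlap_rate:
                second = str(CONCERN_AREAS[int(rng.choice(len(CONCERN_AREAS), p=area_p))])
                areas.add(second)
            follow_up = str(FOLLOW_UP_LEVELS[int(rng.choice(len(FOLLOW_UP_LEVELS), p=level_p))])
            records.append(
                ConcernRecord(call_id=call.call_id, rater_id=rater, concern_areas=areas, follow_up=follow_up)
            )
        else:
            records.append(ConcernRecord(call_id=call.call_id, rater_id=rater))
    return records
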