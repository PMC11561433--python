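"""Inpatient utilization indicators and their association with focus calls.

Admissions are windowed to each patient's study timeframe — 183 days (six
months) before intervention start through 183 days after intervention end —
keeping non-elective stays admitted inside the window.  Two per-patient
indicators result: the number of admissions and the average length of stay
(LOS) per admission, proxies for the frequency and degree of health
worsening.  Patients with no windowed admissions keep count 0 but have no
defined average LOS and are excluded from LOS analyses.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .corpus import AdmissionRecord, CohortDataset, PatientProfile
from .stats import (
    CorrelationResult,
    EffectSizeResult,
    cohens_d,
    holm_bonferroni,
    spearman_test,
)

WINDOW_DAYS = 183  # fixed day-count convention for "6 months"


@dataclass(frozen=True)
class UtilizationSummary:
    """Per-patient utilization indicators next to the focus-call count."""

    patient_id: str
    n_admissions: int
    avg_los: Optional[float]  # None when n_admissions == 0
    n_focus_calls: int

    @property
    def has_focus_call(self) -> bool:
        return self.n_focus_calls > 0


def filter_admissions_window(
    admissions: list[AdmissionRecord], profile: PatientProfile, window_days: int = WINDOW_DAYS
) -> list[AdmissionRecord]:
    """Non-elective admissions admitted within the patient's study window.

    The window is [intervention_start - window_days, intervention_end +
    window_days], inclusive at both ends, keyed on the admission date only
    (a stay straddling the boundary counts if admitted inside).
    """
    lo = profile.intervention_start - datetime.timedelta(days=window_days)
    hi = profile.intervention_end + datetime.timedelta(days=window_days)
    return [a for a in admissions if not a.elective and lo <= a.admit_date <= hi]


def average_los(admissions: list[AdmissionRecord]) -> float:
    """Cumulative bed days divided by the number of admissions."""
    if not admissions:
        raise ValueError("average LOS undefined with zero admissions")
    return sum(a.length_of_stay for a in admissions) / len(admissions)


def build_utilization_summaries(
    dataset: CohortDataset, focus_call_counts: dict[str, int], window_days: int = WINDOW_DAYS
) -> list[UtilizationSummary]:
    """One summary per patient: windowed admission count, average LOS, focus calls."""
    summaries = []
    for profile in dataset.patients:
        kept = filter_admissions_window(
            dataset.admissions_for(profile.patient_id), profile, window_days
        )
        summaries.append(
            UtilizationSummary(
                patient_id=profile.patient_id,
                n_admissions=len(kept),
                avg_los=average_los(kept) if kept else None,
                n_focus_calls=focus_call_counts.get(profile.patient_id, 0),
            )
        )
    return summaries


def associate_focus_with_utilization(
    summaries: list[UtilizationSummary],
) -> dict[str, CorrelationResult]:
    """Spearman tests of focus-call count vs average LOS and vs admission count.

    The two p-values form one Holm-Bonferroni family.  The LOS test uses only
    patients with a defined average LOS; the count test uses all patients.
    """
    los_pairs = [(s.n_focus_calls, s.avg_los) for s in summaries if s.avg_los is not None]
    count_pairs = [(s.n_focus_calls, s.n_admissions) for s in summaries]
    if len(los_pairs) < 3 or len(count_pairs) < 3:
        raise ValueError("need at least 3 patients with defined indicators per test")

    los_res = spearman_test([p[0] for p in los_pairs], [p[1] for p in los_pairs])
    count_res = spearman_test([p[0] for p in count_pairs], [p[1] for p in count_pairs])
    adjusted = holm_bonferroni([los_res.p_value, count_res.p_value]).adjusted
    return {
        "avg_los": CorrelationResult(los_res.rho, los_res.p_value, adjusted[0], los_res.n),
        "n_admissions": CorrelationResult(count_res.rho, count_res.p_value, adjusted[1], count_res.n),
    }


def compare_focus_groups(summaries: list[UtilizationSummary]) -> dict[str, EffectSizeResult]:
    """Cohen d comparing patients with >=1 focus call against those with none.

    Descriptive only (no test): effect sizes for average LOS and admission
    count, group defined by ``has_focus_call``.  Ordering is (with focus
    calls) minus (without), so a negative d means lower utilization in the
    focus-call group.
    """
    with_focus = [s for s in summaries if s.has_focus_call]
    without = [s for s in summaries if not s.has_focus_call]
    if len(with_focus) < 2 or len(without) < 2:
        raise ValueError("both groups need at least 2 patients for an effect size")

    results = {
        "n_admissions": cohens_d(
            [s.n_admissions for s in with_focus], [s.n_admissions for s in without]
        )
    }
    los_a = [s.avg_los for s in with_focus if s.avg_los is not None]
    los_b = [s.avg_los for s in without if s.avg_los is not None]
    if len(los_a) < 2 or len(los_b) < 2:
        raise ValueError("both groups need at least 2 patients with defined average LOS")
    results["avg_los"] = cohens_d(los_a, los_b)
    return results


def summaries_to_frame(summaries: list[UtilizationSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": s.patient_id,
                "n_focus_calls": s.n_focus_calls,
                "n_admissions": s.n_admissions,
                "avg_los": s.avg_los,
            }
            for s in sorted(summaries, key=lambda s: s.patient_id)
        ],
        columns=["patient_id", "n_focus_calls", "n_admissions", "avg_los"],
    )
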