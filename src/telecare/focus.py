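"""Detection of topic-focused calls in per-patient call trajectories.

For each patient the share of utterances on a target topic (by default
lifestyle management) is tracked across their merged, date-ordered calls.
A call is *focused* when its topic ratio rises above the patient's own
median-regression trend line AND either jumps substantially relative to the
previous call or stays heightened after such a jump.  The norm is
patient-specific — no cohort-wide ratio threshold exists — which keeps the
quantification of conversational behaviour personalised to each patient's
trajectory.

Classification is a three-way partition: ``lifestyle_focused``,
``content_not_focused`` (the topic occurs but the call is not focused) and
``no_content`` (zero utterances on the topic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .corpus import AnnotatedCall, CohortDataset, merge_same_day_calls

FOCUSED = "lifestyle_focused"
CONTENT_NOT_FOCUSED = "content_not_focused"
NO_CONTENT = "no_content"
GROUPS = (FOCUSED, CONTENT_NOT_FOCUSED, NO_CONTENT)


@dataclass(frozen=True)
class TopicRatioPoint:
    """Per-call topic share, ordered within a patient's trajectory."""

    call_id: str
    order: int
    ratio: float
    topic_count: int
    total_count: int


@dataclass(frozen=True)
class TrendLine:
    """A patient's per-trajectory ratio norm: ratio ≈ intercept + slope * order."""

    intercept: float
    slope: float
    fit_method: str  # "median_regression" | "constant_median"

    def value_at(self, order: int) -> float:
        return self.intercept + self.slope * order


class FocusConfig(BaseModel):
    """Tunable parameters of the focus-call rule.

    The qualitative criteria "substantially heightened" and "remained
    heightened" are quantified as absolute ratio thresholds: a jump of at
    least ``delta_jump`` over the previous call, and a drop of at most
    ``delta_sustain`` from a focused predecessor.  Trajectories shorter than
    ``min_calls_for_fit`` fall back to a constant line at the median ratio.
    """

    topic: str = "lifestyle_management"
    delta_jump: float = Field(default=0.05, ge=0)
    delta_sustain: float = Field(default=0.02, ge=0)
    min_calls_for_fit: int = Field(default=4, ge=2)


@dataclass(frozen=True)
class FocusLabel:
    """Classification of one call, with the rule that produced it."""

    call_id: str
    group: str  # one of GROUPS
    rule_fired: str  # "jump" | "sustained" | "none"
    above_trend: bool


@dataclass
class PartitionResult:
    """Per-patient focus labels plus cohort-level group totals."""

    labels: dict[str, list[FocusLabel]]  # patient_id -> labels in trajectory order
    points: dict[str, list[TopicRatioPoint]]
    trends: dict[str, TrendLine]
    review_queue: pd.DataFrame = field(default_factory=pd.DataFrame)

    def label_map(self) -> dict[str, FocusLabel]:
        return {lab.call_id: lab for labs in self.labels.values() for lab in labs}

    def group_counts(self, patient_id: Optional[str] = None) -> dict[str, int]:
        if patient_id is None:
            labs = [lab for labs in self.labels.values() for lab in labs]
        else:
            labs = self.labels.get(patient_id, [])
        return {g: sum(1 for lab in labs if lab.group == g) for g in GROUPS}

    def focus_call_counts(self) -> dict[str, int]:
        """Per-patient count of focused calls (patients with no calls -> 0)."""
        return {
            pid: sum(1 for lab in labs if lab.group == FOCUSED)
            for pid, labs in self.labels.items()
        }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pid, labs in sorted(self.labels.items()):
            pts = self.points[pid]
            for lab, pt in zip(labs, pts):
                rows.append(
                    {
                        "patient_id": pid,
                        "call_id": lab.call_id,
                        "order": pt.order,
                        "ratio": pt.ratio,
                        "group": lab.group,
                        "rule_fired": lab.rule_fired,
                        "above_trend": lab.above_trend,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=["patient_id", "call_id", "order", "ratio", "group", "rule_fired", "above_trend"],
        )


# ---------------------------------------------------------------------------
# Operations

def compute_topic_ratios(calls: list[AnnotatedCall], topic: str) -> list[TopicRatioPoint]:
    """Utterance ratio of ``topic`` for each call of one patient's sequence.

    The ratio is the call's utterance count on the topic divided by its total
    utterance count across all topics.  ``calls`` must already be merged and
    date-sorted; order positions are assigned contiguously from 0.
    """
    points = []
    for order, call in enumerate(calls):
        total = call.n_utterances
        count = sum(1 for u in call.utterances if u.topic == topic)
        points.append(
            TopicRatioPoint(
                call_id=call.call_id,
                order=order,
                ratio=count / total,
                topic_count=count,
                total_count=total,
            )
        )
    return points


def fit_median_trend(points: list[TopicRatioPoint], config: FocusConfig) -> TrendLine:
    """Median (tau = 0.5 quantile) regression of ratio on call order.

    The returned line minimises the summed absolute residuals.  The L1
    minimiser can be non-unique; any optimal line is acceptable and tests
    compare objective values rather than coefficients.  Trajectories shorter
    than ``config.min_calls_for_fit`` get a constant line at the median
    ratio instead (a 2- or 3-point median regression interpolates and would
    forbid any call from sitting above its own trend).
    """
    if not points:
        raise ValueError("fit_median_trend requires at least one point")
    ratios = np.array([p.ratio for p in points], dtype=float)
    if len(points) < config.min_calls_for_fit:
        return TrendLine(intercept=float(np.median(ratios)), slope=0.0, fit_method="constant_median")
    if np.ptp(ratios) == 0.0:
        # degenerate: the flat line through the common value is exactly optimal
        return TrendLine(intercept=float(ratios[0]), slope=0.0, fit_method="median_regression")

    import statsmodels.api as sm

    orders = np.array([p.order for p in points], dtype=float)
    X = sm.add_constant(orders)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.QuantReg(ratios, X).fit(q=0.5)
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    if not (np.isfinite(intercept) and np.isfinite(slope)):  # pragma: no cover
        return TrendLine(intercept=float(np.median(ratios)), slope=0.0, fit_method="constant_median")
    return TrendLine(intercept=intercept, slope=slope, fit_method="median_regression")


def classify_focus_calls(
    points: list[TopicRatioPoint], trend: TrendLine, config: FocusConfig
) -> list[FocusLabel]:
    """Apply the focus rule along one trajectory.

    Call *i* is focused iff it has topic content, its ratio strictly exceeds
    the trend value at its order, and either

    * **jump** — its ratio exceeds the previous call's by at least
      ``delta_jump`` (the virtual call before the first has ratio 0), or
    * **sustained** — the previous call is focused and the ratio has not
      dropped by more than ``delta_sustain``.

    Ties with the trend line go to not-focused: a deviation from the norm
    must exceed the norm.
    """
    labels: list[FocusLabel] = []
    for i, pt in enumerate(points):
        above = pt.ratio > trend.value_at(pt.order)
        if pt.topic_count == 0:
            labels.append(FocusLabel(pt.call_id, NO_CONTENT, "none", above))
            continue
        prev_ratio = points[i - 1].ratio if i > 0 else 0.0
        prev_focused = bool(labels) and labels[-1].group == FOCUSED
        rule = "none"
        if above:
            if pt.ratio - prev_ratio >= config.delta_jump:
                rule = "jump"
            elif prev_focused and pt.ratio >= prev_ratio - config.delta_sustain:
                rule = "sustained"
        group = FOCUSED if rule != "none" else CONTENT_NOT_FOCUSED
        labels.append(FocusLabel(pt.call_id, group, rule, above))
    return labels


def partition_calls(
    dataset: CohortDataset, config: Optional[FocusConfig] = None
) -> PartitionResult:
    """Classify every patient's merged calls into the three focus groups.

    Calls are merged by (patient, date) first, so the trajectory matches the
    one-conversation-per-day convention.  Borderline calls — above their
    trend but failing the jump/sustained criterion — are listed in a review
    queue, the deterministic stand-in for manual adjudication.
    """
    config = config or FocusConfig()
    labels: dict[str, list[FocusLabel]] = {}
    points: dict[str, list[TopicRatioPoint]] = {}
    trends: dict[str, TrendLine] = {}
    review_rows = []
    for profile in dataset.patients:
        pid = profile.patient_id
        calls = merge_same_day_calls(dataset.calls_for(pid))
        if not calls:
            labels[pid], points[pid] = [], []
            continue
        pts = compute_topic_ratios(calls, config.topic)
        trend = fit_median_trend(pts, config)
        labs = classify_focus_calls(pts, trend, config)
        labels[pid], points[pid], trends[pid] = labs, pts, trend
        for lab, pt in zip(labs, pts):
            if lab.above_trend and lab.group == CONTENT_NOT_FOCUSED:
                review_rows.append(
                    {"patient_id": pid, "call_id": lab.call_id, "order": pt.order, "ratio": pt.ratio}
                )
    queue = pd.DataFrame(review_rows, columns=["patient_id", "call_id", "order", "ratio"])
    return PartitionResult(labels=labels, points=points, trends=trends, review_queue=queue)
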