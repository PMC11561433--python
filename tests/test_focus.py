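"""Focus-call detection: ratios, median trend, classification rule, partition."""

import datetime

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telecare.corpus import CohortDataset
from telecare.focus import (
    CONTENT_NOT_FOCUSED,
    FOCUSED,
    NO_CONTENT,
    FocusConfig,
    TopicRatioPoint,
    TrendLine,
    classify_focus_calls,
    compute_topic_ratios,
    fit_median_trend,
    partition_calls,
)

from conftest import make_call, make_patient

TOPIC = "lifestyle_management"


def points_from_ratios(ratios, denom=1000):
    return [
        TopicRatioPoint(f"c{i}", i, r, round(r * denom), denom) for i, r in enumerate(ratios)
    ]


def check_loss(points, intercept, slope):
    return sum(abs(p.ratio - (intercept + slope * p.order)) for p in points)


def brute_force_labels(points, trend, config):
    """Literal re-implementation of the rule text, independent of telecare.focus."""
    groups = []
    for i, pt in enumerate(points):
        if pt.topic_count == 0:
            groups.append(NO_CONTENT)
            continue
        above = pt.ratio > trend.intercept + trend.slope * pt.order
        prev = points[i - 1].ratio if i > 0 else 0.0
        jump = pt.ratio - prev >= config.delta_jump
        sustained = (
            i > 0 and groups[i - 1] == FOCUSED and pt.ratio >= prev - config.delta_sustain
        )
        groups.append(FOCUSED if above and (jump or sustained) else CONTENT_NOT_FOCUSED)
    return groups


class TestTopicRatios:
    @pytest.mark.parametrize(
        "plan,expected",
        [
            ({"vitals": 100}, 0.0),
            ({TOPIC: 7}, 1.0),
            ({TOPIC: 10, "vitals": 190}, 0.05),
        ],
    )
    def test_ratio_arithmetic(self, plan, expected):
        call = make_call("c", "A", datetime.date(2015, 1, 1), plan)
        (pt,) = compute_topic_ratios([call], TOPIC)
        assert pt.ratio == expected
        assert pt.total_count == sum(plan.values())

    def test_orders_contiguous_and_normalized(self):
        calls = [
            make_call(f"c{i}", "A", datetime.date(2015, 1, 1 + i), {TOPIC: i + 1, "vitals": 9 - i})
            for i in range(4)
        ]
        pts = compute_topic_ratios(calls, TOPIC)
        assert [p.order for p in pts] == [0, 1, 2, 3]
        assert all(0 <= p.ratio <= 1 and p.ratio == p.topic_count / p.total_count for p in pts)


class TestMedianTrend:
    def test_constant_ratios_give_flat_line(self):
        trend = fit_median_trend(points_from_ratios([0.05] * 5), FocusConfig())
        assert trend.slope == 0.0 and trend.intercept == pytest.approx(0.05)
        assert check_loss(points_from_ratios([0.05] * 5), trend.intercept, trend.slope) == 0

    def test_exact_line_recovered(self):
        ratios = [0.01 + 0.002 * i for i in range(6)]
        trend = fit_median_trend(points_from_ratios(ratios), FocusConfig())
        assert trend.intercept == pytest.approx(0.01, abs=1e-6)
        assert trend.slope == pytest.approx(0.002, abs=1e-6)

    def test_short_trajectory_falls_back_to_constant_median(self):
        trend = fit_median_trend(points_from_ratios([0.1, 0.3, 0.2]), FocusConfig())
        assert trend.fit_method == "constant_median"
        assert (trend.intercept, trend.slope) == (0.2, 0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_check_loss_is_grid_minimal(self, seed):
        rng = np.random.default_rng(seed)
        pts = points_from_ratios(np.round(rng.uniform(0, 0.2, size=6), 3).tolist())
        trend = fit_median_trend(pts, FocusConfig())
        assert trend.fit_method == "median_regression"
        fit_loss = check_loss(pts, trend.intercept, trend.slope)
        grid = min(
            check_loss(pts, a, b)
            for a in np.linspace(-0.1, 0.3, 161)
            for b in np.linspace(-0.06, 0.06, 121)
        )
        assert fit_loss <= grid + 1e-9


class TestClassification:
    def test_all_zero_ratios_are_no_content(self):
        pts = points_from_ratios([0.0] * 5)
        labs = classify_focus_calls(pts, fit_median_trend(pts, FocusConfig()), FocusConfig())
        assert all(lab.group == NO_CONTENT for lab in labs)

    def test_jump_then_sustained_sequence(self):
        # ratios rise at order 2 (jump +0.08) and stay high at order 3
        # (drop 0.01 within the sustain tolerance under a focused predecessor)
        pts = points_from_ratios([0.01, 0.02, 0.10, 0.09, 0.01])
        cfg = FocusConfig()
        trend = fit_median_trend(pts, cfg)
        assert check_loss(pts, trend.intercept, trend.slope) == pytest.approx(0.16, abs=1e-9)
        labs = classify_focus_calls(pts, trend, cfg)
        assert [(l.group, l.rule_fired) for l in labs] == [
            (CONTENT_NOT_FOCUSED, "none"),
            (CONTENT_NOT_FOCUSED, "none"),
            (FOCUSED, "jump"),
            (FOCUSED, "sustained"),
            (CONTENT_NOT_FOCUSED, "none"),
        ]

    def test_tie_with_trend_is_not_focused(self):
        pts = points_from_ratios([0.2])
        cfg = FocusConfig()
        trend = fit_median_trend(pts, cfg)
        assert trend.fit_method == "constant_median" and trend.intercept == 0.2
        (lab,) = classify_focus_calls(pts, trend, cfg)
        assert lab.group == CONTENT_NOT_FOCUSED and not lab.above_trend

    def test_first_call_can_fire_jump_from_zero(self):
        pts = points_from_ratios([0.3, 0.0, 0.0])
        labs = classify_focus_calls(pts, TrendLine(0.05, 0.0, "constant_median"), FocusConfig())
        assert labs[0].group == FOCUSED and labs[0].rule_fired == "jump"

    @given(
        ratios=st.lists(
            st.sampled_from([i / 50 for i in range(11)]), min_size=1, max_size=8
        ),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_matches_brute_force_rule(self, ratios, seed):
        pts = points_from_ratios(ratios, denom=50)
        cfg = FocusConfig()
        trend = fit_median_trend(pts, cfg)
        labs = classify_focus_calls(pts, trend, cfg)
        assert [l.group for l in labs] == brute_force_labels(pts, trend, cfg)

    def test_raising_delta_jump_never_adds_focused_calls(self):
        rng = np.random.default_rng(3)
        pts = points_from_ratios(np.round(rng.uniform(0, 0.3, size=10), 2).tolist())
        trend = fit_median_trend(pts, FocusConfig())
        prev_count = None
        for dj in [0.0, 0.02, 0.05, 0.1, 0.2, 0.5]:
            cfg = FocusConfig(delta_jump=dj, delta_sustain=0.0)
            n = sum(l.group == FOCUSED for l in classify_focus_calls(pts, trend, cfg))
            if prev_count is not None:
                assert n <= prev_count
            prev_count = n

    def test_labels_scale_free_in_utterance_counts(self):
        plans = [{TOPIC: 1, "vitals": 9}, {TOPIC: 3, "vitals": 7}, {TOPIC: 0, "vitals": 5}, {TOPIC: 2, "vitals": 8}]
        cfg = FocusConfig()
        label_sets = []
        for scale in (1, 7):
            calls = [
                make_call(f"c{i}", "A", datetime.date(2015, 1, 1 + i), {t: n * scale for t, n in p.items()})
                for i, p in enumerate(plans)
            ]
            pts = compute_topic_ratios(calls, TOPIC)
            labs = classify_focus_calls(pts, fit_median_trend(pts, cfg), cfg)
            label_sets.append([(l.group, l.rule_fired) for l in labs])
            assert [p.ratio for p in pts] == [0.1, 0.3, 0.0, 0.2]
        assert label_sets[0] == label_sets[1]


class TestPartition:
    def test_no_content_cohort(self):
        ds = CohortDataset(
            patients=[make_patient("A")],
            calls=[
                make_call(f"c{i}", "A", datetime.date(2015, 1, 1 + i), {"vitals": 5})
                for i in range(3)
            ],
        )
        part = partition_calls(ds)
        assert part.group_counts() == {FOCUSED: 0, CONTENT_NOT_FOCUSED: 0, NO_CONTENT: 3}

    def test_groups_partition_all_calls(self, small_synthetic):
        ds, _ = small_synthetic
        part = partition_calls(ds)
        for pid in (p.patient_id for p in ds.patients):
            counts = part.group_counts(pid)
            assert sum(counts.values()) == len(ds.calls_for(pid))
        assert sum(part.group_counts().values()) == len(ds.calls)

    def test_review_queue_lists_above_trend_non_focused(self, small_synthetic):
        ds, _ = small_synthetic
        part = partition_calls(ds)
        labels = part.label_map()
        for row in part.review_queue.itertuples():
            lab = labels[row.call_id]
            assert lab.above_trend and lab.group == CONTENT_NOT_FOCUSED
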