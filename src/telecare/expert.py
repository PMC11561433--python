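"""Tabulation of expert concern evaluations.

Experienced telecarers review calls and record areas of concern (possibly
several per call) plus a follow-up level.  This module crosses concern
areas with follow-up levels for all assessed calls and for the
lifestyle-focused stratum, computes flagged proportions, and resolves
overlap-aware union counts by inclusion-exclusion.  Calls are counted once
per area they carry, so area columns overlap by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional

import pandas as pd

from .corpus import CONCERN_AREAS, FOLLOW_UP_LEVELS, ConcernRecord, VocabularyError
from .focus import FOCUSED, FocusLabel

_ESCALATION = {level: i for i, level in enumerate(FOLLOW_UP_LEVELS)}


@dataclass
class ConcernTable:
    """Concern-area x follow-up-level counts, per stratum.

    ``counts[stratum]`` is a DataFrame with follow-up levels as rows and
    concern areas as columns; ``n_assessed``/``n_flagged`` hold stratum call
    totals.  Strata are ``"all"`` and ``"lifestyle_focused"``; the focused
    stratum is a sub-table of the all-calls one.
    """

    counts: dict[str, pd.DataFrame]
    area_totals: dict[str, dict[str, int]]
    n_assessed: dict[str, int]
    n_flagged: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for stratum, frame in self.counts.items():
            block = frame.copy()
            block.insert(0, "stratum", stratum)
            block.insert(1, "follow_up", frame.index)
            frames.append(block.reset_index(drop=True))
        return pd.concat(frames, ignore_index=True)


def _resolve_duplicates(records: Iterable[ConcernRecord]) -> list[ConcernRecord]:
    """Collapse multiple ratings of one call (pilot phase) to a single record.

    Resolution takes the union of the concern areas and the most escalated
    follow-up level across raters.
    """
    by_call: dict[str, list[ConcernRecord]] = {}
    for rec in records:
        by_call.setdefault(rec.call_id, []).append(rec)
    resolved = []
    for call_id, recs in by_call.items():
        if len(recs) == 1:
            resolved.append(recs[0])
            continue
        areas = set().union(*(r.concern_areas for r in recs))
        levels = [r.follow_up for r in recs if r.follow_up is not None]
        follow_up = max(levels, key=_ESCALATION.__getitem__) if levels else None
        resolved.append(
            ConcernRecord(
                call_id=call_id,
                rater_id="+".join(sorted({r.rater_id for r in recs})),
                concern_areas=areas,
                follow_up=follow_up,
            )
        )
    return resolved


def tabulate_concerns(
    records: list[ConcernRecord], labels: dict[str, FocusLabel]
) -> ConcernTable:
    """Cross concern areas with follow-up levels, overall and for focused calls.

    Every assessed call must carry a focus label.  A call with areas
    {a, b} at level L contributes +1 to both (L, a) and (L, b) — overlaps are
    preserved — but counts once in the flagged total.
    """
    for rec in records:
        unknown = rec.concern_areas - set(CONCERN_AREAS)
        if unknown:
            raise VocabularyError(f"unknown concern area(s) {sorted(unknown)}")
        if rec.call_id not in labels:
            raise KeyError(f"call {rec.call_id} has no focus label")

    resolved = _resolve_duplicates(records)
    strata = {
        "all": resolved,
        "lifestyle_focused": [r for r in resolved if labels[r.call_id].group == FOCUSED],
    }
    counts, area_totals, n_assessed, n_flagged = {}, {}, {}, {}
    for stratum, recs in strata.items():
        frame = pd.DataFrame(0, index=list(FOLLOW_UP_LEVELS), columns=list(CONCERN_AREAS))
        totals = dict.fromkeys(CONCERN_AREAS, 0)
        flagged = 0
        for rec in recs:
            if rec.flagged:
                flagged += 1
            for area in rec.concern_areas:
                totals[area] += 1
                if rec.follow_up is not None:
                    frame.loc[rec.follow_up, area] += 1
        counts[stratum] = frame
        area_totals[stratum] = totals
        n_assessed[stratum] = len(recs)
        n_flagged[stratum] = flagged
    return ConcernTable(counts=counts, area_totals=area_totals, n_assessed=n_assessed, n_flagged=n_flagged)


def flagged_proportion(table: ConcernTable, stratum: str = "all") -> float:
    """Percentage of assessed calls with >=1 concern area, rounded to 1 decimal."""
    assessed = table.n_assessed.get(stratum, 0)
    if assessed == 0:
        raise ValueError(f"no assessed calls in stratum {stratum!r}")
    return round(100.0 * table.n_flagged[stratum] / assessed, 1)


def union_concern_count(
    table: ConcernTable,
    areas: Iterable[str],
    overlaps: Optional[dict[frozenset, int]] = None,
    stratum: str = "all",
) -> int:
    """Number of distinct calls carrying any of the given areas.

    Inclusion-exclusion from per-area totals and the supplied pairwise
    overlap counts (missing pairs are treated as disjoint).  Overlap terms
    of order 3 and higher must be supplied explicitly; otherwise requesting
    more than 2 areas is an error, since pairwise information alone cannot
    determine the union.
    """
    overlaps = overlaps or {}
    areas = list(dict.fromkeys(areas))
    unknown = set(areas) - set(CONCERN_AREAS)
    if unknown:
        raise VocabularyError(f"unknown concern area(s) {sorted(unknown)}")
    totals = table.area_totals[stratum]

    for pair in combinations(areas, 2):
        ov = overlaps.get(frozenset(pair), 0)
        if ov > min(totals[pair[0]], totals[pair[1]]):
            raise ValueError(f"overlap for {pair} exceeds an area total")
    if len(areas) > 2:
        needed = [frozenset(c) for k in range(3, len(areas) + 1) for c in combinations(areas, k)]
        if any(key not in overlaps for key in needed):
            raise ValueError("unions over >2 areas require explicit higher-order overlap counts")

    union = 0
    for k in range(1, len(areas) + 1):
        sign = (-1) ** (k + 1)
        for combo in combinations(areas, k):
            if k == 1:
                union += totals[combo[0]]
            else:
                union += sign * overlaps.get(frozenset(combo), 0)
    return union
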