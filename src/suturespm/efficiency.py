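"""Uni- and bi-manual efficiency metrics from interval algebra.

A hand's activity is *productive* when its label carries one of the four
targets of interest; ``idle`` and ``not_visible`` time is nonproductive.
With T the total annotated duration of an analysis unit (a suture or one of
its segments) and t_w the hand's nonproductive time,

    S_eff = (T - t_w) / T

is the suturing efficiency of that hand, and with t_B the total time during
which *both* hands are simultaneously productive,

    B_eff = t_B / T

is the bimanual efficiency.  All three lie in [0, 1], and B_eff can never
exceed either hand's S_eff.  The bimanual overlap is computed by exact
interval intersection of the two hands' productive time sets (event-boundary
sweep), never by sampling.

At suture level T is the sum of the suture's annotated segment durations;
off-camera stretches the annotator excluded between segments contribute
nothing.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .annotation_model import (
    AnnotatedInterval,
    AnnotationDataset,
    SegmentAnnotation,
)

__all__ = [
    "EfficiencyError",
    "nonproductive_time",
    "suturing_efficiency",
    "bimanual_productive_time",
    "efficiency_table",
    "EFFICIENCY_COLUMNS",
]

EFFICIENCY_COLUMNS = (
    "participant_id",
    "group",
    "suture_index",
    "segment_type",
    "level",
    "s_eff_left",
    "s_eff_right",
    "b_eff",
    "total_time_s",
)

_SPAN_TOL = 1e-6


class EfficiencyError(ValueError):
    """Raised for degenerate inputs (zero duration, mismatched hand spans)."""


def nonproductive_time(intervals: Iterable[AnnotatedInterval]) -> float:
    """Total seconds labeled idle or not_visible."""
    return sum(iv.duration for iv in intervals if not iv.label.is_productive)


def suturing_efficiency(intervals: Sequence[AnnotatedInterval]) -> float:
    """(T - t_w) / T for one hand's interval sequence."""
    total = sum(iv.duration for iv in intervals)
    if total <= 0:
        raise EfficiencyError("cannot compute efficiency of a zero-duration sequence")
    return (total - nonproductive_time(intervals)) / total


def _productive_spans(intervals: Sequence[AnnotatedInterval]) -> list[tuple[float, float]]:
    """Maximal productive [start, end) spans, merged across adjacent intervals."""
    spans: list[tuple[float, float]] = []
    for iv in intervals:
        if not iv.label.is_productive:
            continue
        if spans and abs(iv.start_s - spans[-1][1]) <= _SPAN_TOL:
            spans[-1] = (spans[-1][0], iv.end_s)
        else:
            spans.append((iv.start_s, iv.end_s))
    return spans


def bimanual_productive_time(
    left: Sequence[AnnotatedInterval], right: Sequence[AnnotatedInterval]
) -> float:
    """Total time both hands are simultaneously productive (exact intersection)."""
    if not left or not right:
        raise EfficiencyError("both hands need at least one interval")
    span_l = (left[0].start_s, left[-1].end_s)
    span_r = (right[0].start_s, right[-1].end_s)
    if abs(span_l[0] - span_r[0]) > _SPAN_TOL or abs(span_l[1] - span_r[1]) > _SPAN_TOL:
        raise EfficiencyError(
            f"hands span different time ranges: left {span_l}, right {span_r}"
        )
    spans_l = _productive_spans(left)
    spans_r = _productive_spans(right)
    total = 0.0
    i = j = 0
    while i < len(spans_l) and j < len(spans_r):
        lo = max(spans_l[i][0], spans_r[j][0])
        hi = min(spans_l[i][1], spans_r[j][1])
        if hi > lo:
            total += hi - lo
        if spans_l[i][1] < spans_r[j][1]:
            i += 1
        else:
            j += 1
    return total


def _segment_stats(seg: SegmentAnnotation) -> tuple[float, float, float, float]:
    """(T, t_w_left, t_w_right, t_B) for one segment."""
    total = seg.duration
    return (
        total,
        nonproductive_time(seg.intervals_left),
        nonproductive_time(seg.intervals_right),
        bimanual_productive_time(seg.intervals_left, seg.intervals_right),
    )


def efficiency_table(dataset: AnnotationDataset, level: str) -> pd.DataFrame:
    """S_eff per hand and B_eff for every suture (or every segment) of a cohort.

    Suture-level T, t_w and t_B are sums over the suture's segments, so the
    suture record is the duration-weighted aggregate of its segment records.
    """
    if level not in ("suture", "segment"):
        raise EfficiencyError(f"level must be 'suture' or 'segment', got {level!r}")
    rows = []
    for participant, suture in dataset.iter_sutures():
        per_seg = []
        for seg in suture.segments:
            try:
                per_seg.append((seg.segment_type, _segment_stats(seg)))
            except EfficiencyError as exc:
                raise EfficiencyError(
                    f"participant {participant.participant_id}, suture "
                    f"{suture.suture_index}, segment {seg.segment_type}: {exc}"
                ) from None
        if level == "segment":
            for seg_type, (total, tw_l, tw_r, tb) in per_seg:
                rows.append(
                    _record(participant, suture.suture_index, seg_type, level,
                            total, tw_l, tw_r, tb)
                )
        else:
            total = sum(s[1][0] for s in per_seg)
            tw_l = sum(s[1][1] for s in per_seg)
            tw_r = sum(s[1][2] for s in per_seg)
            tb = sum(s[1][3] for s in per_seg)
            rows.append(
                _record(participant, suture.suture_index, None, level,
                        total, tw_l, tw_r, tb)
            )
    return pd.DataFrame(rows, columns=list(EFFICIENCY_COLUMNS))


def _record(participant, suture_index, segment_type, level, total, tw_l, tw_r, tb) -> dict:
    if total <= 0:
        raise EfficiencyError("zero total duration")
    return {
        "participant_id": participant.participant_id,
        "group": participant.group,
        "suture_index": suture_index,
        "segment_type": segment_type,
        "level": level,
        "s_eff_left": (total - tw_l) / total,
        "s_eff_right": (total - tw_r) / total,
        "b_eff": tb / total,
        "total_time_s": total,
    }
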