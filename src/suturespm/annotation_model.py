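"""Domain model for movement-level annotations of bimanual suturing tasks.

A suturing task is decomposed top-down into five ordered segments (needle
transport, piercing, three knots) and bottom-up into elementary activities of
each hand's tool: an ``<action;target>`` tuple drawn from four actions (move,
transport, hold_still, grasp) and four targets of interest (needle, incision,
thread, tool), plus two special labels for nonproductive time (``idle``) and
time when the tool is outside the field of view (``not_visible``).  That
yields 18 possible activity labels, 16 of which carry a target.

This module defines the annotation containers, the plain-text annotation file
format, validation of the interval-algebra invariants (per hand, intervals
tile each segment contiguously without overlap), and the preprocessing rule
that merges very short activities (< 0.5 s by default) into their neighbour.

Times are continuous seconds from the start of the task.  Frame rates are
never assumed.  Gaps inside a segment are rejected rather than imputed: the
annotator must label waiting time explicitly as ``idle`` or ``not_visible``,
which keeps the nonproductive-time bookkeeping of the efficiency metrics
unambiguous.  Stretches the annotator excluded (e.g. movement entirely
off-camera between segments) are simply absent from the file; total task time
is always the sum of annotated segment durations.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence, TextIO, Union

__all__ = [
    "ACTIONS",
    "TARGETS",
    "SPECIAL_ACTIONS",
    "SEGMENT_TYPES",
    "HANDS",
    "GROUPS",
    "ANNOTATION_COLUMNS",
    "AnnotationError",
    "ActivityLabel",
    "AnnotatedInterval",
    "SegmentAnnotation",
    "SutureAnnotation",
    "ParticipantRecord",
    "AnnotationDataset",
    "read_annotations",
    "write_annotations",
    "merge_short_activities",
    "preprocess_dataset",
]

ACTIONS = ("move", "transport", "hold_still", "grasp")
TARGETS = ("needle", "incision", "thread", "tool")
SPECIAL_ACTIONS = ("idle", "not_visible")
SEGMENT_TYPES = ("needle_transport", "piercing", "knot1", "knot2", "knot3")
HANDS = ("left", "right")
GROUPS = ("novice", "expert")

#: header of the delimited annotation file, in order
ANNOTATION_COLUMNS = (
    "participant_id",
    "group",
    "handedness",
    "suture",
    "segment",
    "hand",
    "start_s",
    "end_s",
    "action",
    "target",
)

#: accepted input spellings normalised on read
_ACTION_ALIASES = {"grab": "grasp", "hold still": "hold_still", "hold-still": "hold_still"}

#: tolerance for contiguity / span comparisons, seconds
_TIME_TOL = 1e-6


class AnnotationError(ValueError):
    """Raised when an annotation file or container violates the model invariants."""


@dataclass(frozen=True)
class ActivityLabel:
    """One of the 18 activity labels: an ``<action;target>`` tuple or a special label.

    ``target`` is ``"none"`` exactly for the two special labels (``idle``,
    ``not_visible``); every one of the four proper actions requires one of the
    four targets of interest.
    """

    action: str
    target: str = "none"

    def __post_init__(self) -> None:
        if self.action in SPECIAL_ACTIONS:
            if self.target != "none":
                raise AnnotationError(
                    f"label {self.action!r} is nonproductive and must have target 'none', "
                    f"got {self.target!r}"
                )
        elif self.action in ACTIONS:
            if self.target not in TARGETS:
                raise AnnotationError(
                    f"action {self.action!r} requires a target in {TARGETS}, got {self.target!r}"
                )
        else:
            raise AnnotationError(f"unknown action {self.action!r}")

    @property
    def is_productive(self) -> bool:
        """True for the 16 action-by-target labels, False for idle / not_visible."""
        return self.target != "none"

    @property
    def key(self) -> str:
        """Canonical string form, e.g. ``'transport;incision'`` or ``'idle'``."""
        return f"{self.action};{self.target}" if self.is_productive else self.action

    @classmethod
    def from_key(cls, key: str) -> "ActivityLabel":
        if ";" in key:
            action, target = key.split(";", 1)
            return cls(action=action, target=target)
        return cls(action=key)

    @classmethod
    def idle(cls) -> "ActivityLabel":
        return cls(action="idle")

    @classmethod
    def not_visible(cls) -> "ActivityLabel":
        return cls(action="not_visible")


def all_labels() -> tuple[ActivityLabel, ...]:
    """The full 18-label vocabulary in canonical order: 16 tuples, then idle, not_visible."""
    labels = [ActivityLabel(a, t) for a in ACTIONS for t in TARGETS]
    labels.append(ActivityLabel.idle())
    labels.append(ActivityLabel.not_visible())
    return tuple(labels)


@dataclass(frozen=True)
class AnnotatedInterval:
    """One timed activity of one hand over ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    hand: str
    label: ActivityLabel

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise AnnotationError(f"unknown hand {self.hand!r}")
        if not self.end_s > self.start_s:
            raise AnnotationError(
                f"interval must have positive duration: [{self.start_s}, {self.end_s})"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s


def _validate_tiling(intervals: Sequence[AnnotatedInterval], context: str) -> None:
    """Check sortedness, non-overlap and contiguity of one hand's intervals."""
    if not intervals:
        raise AnnotationError(f"{context}: empty interval sequence")
    for prev, cur in zip(intervals, intervals[1:]):
        if cur.start_s < prev.end_s - _TIME_TOL:
            raise AnnotationError(
                f"{context}: intervals overlap at t={cur.start_s:g} "
                f"(previous ends at {prev.end_s:g})"
            )
        if cur.start_s > prev.end_s + _TIME_TOL:
            raise AnnotationError(
                f"{context}: gap between t={prev.end_s:g} and t={cur.start_s:g}; "
                "unlabeled time must be annotated idle or not_visible"
            )


@dataclass(frozen=True)
class SegmentAnnotation:
    """Both hands' interval sequences over one segment of a suture.

    Each hand's intervals tile the segment span contiguously, and the two
    hands span the same ``[start, end]``.
    """

    segment_type: str
    intervals_left: tuple[AnnotatedInterval, ...]
    intervals_right: tuple[AnnotatedInterval, ...]

    def __post_init__(self) -> None:
        if self.segment_type not in SEGMENT_TYPES:
            raise AnnotationError(f"unknown segment type {self.segment_type!r}")
        object.__setattr__(self, "intervals_left", tuple(self.intervals_left))
        object.__setattr__(self, "intervals_right", tuple(self.intervals_right))
        for hand, seq in (("left", self.intervals_left), ("right", self.intervals_right)):
            _validate_tiling(seq, f"segment {self.segment_type}, {hand} hand")
            for iv in seq:
                if iv.hand != hand:
                    raise AnnotationError(
                        f"segment {self.segment_type}: interval with hand={iv.hand!r} "
                        f"in the {hand}-hand sequence"
                    )
        if (
            abs(self.intervals_left[0].start_s - self.intervals_right[0].start_s) > _TIME_TOL
            or abs(self.intervals_left[-1].end_s - self.intervals_right[-1].end_s) > _TIME_TOL
        ):
            raise AnnotationError(
                f"segment {self.segment_type}: hands span different time ranges "
                f"(left [{self.intervals_left[0].start_s:g}, {self.intervals_left[-1].end_s:g}], "
                f"right [{self.intervals_right[0].start_s:g}, {self.intervals_right[-1].end_s:g}])"
            )

    @property
    def start_s(self) -> float:
        return self.intervals_left[0].start_s

    @property
    def end_s(self) -> float:
        return self.intervals_left[-1].end_s

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    def intervals(self, hand: str) -> tuple[AnnotatedInterval, ...]:
        if hand == "left":
            return self.intervals_left
        if hand == "right":
            return self.intervals_right
        raise AnnotationError(f"unknown hand {hand!r}")


@dataclass(frozen=True)
class SutureAnnotation:
    """One suture: segments in the canonical order, each type at most once.

    A complete suture has all five segment types; incomplete sutures (e.g.
    missing the third knot) simply omit the trailing segments.
    """

    suture_index: int
    segments: tuple[SegmentAnnotation, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if self.suture_index < 1:
            raise AnnotationError(f"suture_index must be >= 1, got {self.suture_index}")
        if not self.segments:
            raise AnnotationError("suture has no segments")
        types = [s.segment_type for s in self.segments]
        ranks = [SEGMENT_TYPES.index(t) for t in types]
        if len(set(types)) != len(types) or ranks != sorted(ranks):
            raise AnnotationError(
                f"suture {self.suture_index}: segment types {types} must appear at most "
                f"once each, in the canonical order {list(SEGMENT_TYPES)}"
            )
        for prev, cur in zip(self.segments, self.segments[1:]):
            if cur.start_s < prev.end_s - _TIME_TOL:
                raise AnnotationError(
                    f"suture {self.suture_index}: segment {cur.segment_type} starts before "
                    f"{prev.segment_type} ends"
                )

    @property
    def is_complete(self) -> bool:
        return len(self.segments) == len(SEGMENT_TYPES)

    def segment(self, segment_type: str) -> SegmentAnnotation | None:
        for s in self.segments:
            if s.segment_type == segment_type:
                return s
        return None


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    group: str
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise AnnotationError(f"unknown group {self.group!r}")
        if self.handedness not in HANDS:
            raise AnnotationError(f"unknown handedness {self.handedness!r}")


@dataclass(frozen=True)
class AnnotationDataset:
    """All annotations of a study cohort: participants and their sutures."""

    participants: tuple[ParticipantRecord, ...]
    annotations: Mapping[str, tuple[SutureAnnotation, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "participants", tuple(self.participants))
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise AnnotationError("duplicate participant_id in dataset")
        object.__setattr__(
            self,
            "annotations",
            {pid: tuple(sutures) for pid, sutures in self.annotations.items()},
        )
        known = set(ids)
        for pid, sutures in self.annotations.items():
            if pid not in known:
                raise AnnotationError(f"annotations for unknown participant {pid!r}")
            if not sutures:
                raise AnnotationError(f"participant {pid!r} has no sutures")
        for pid in known:
            if pid not in self.annotations:
                raise AnnotationError(f"participant {pid!r} listed without annotations")

    def participant(self, participant_id: str) -> ParticipantRecord:
        for p in self.participants:
            if p.participant_id == participant_id:
                return p
        raise KeyError(participant_id)

    @property
    def n_sutures(self) -> int:
        return sum(len(s) for s in self.annotations.values())

    @property
    def n_segments(self) -> int:
        return sum(len(su.segments) for s in self.annotations.values() for su in s)

    def iter_sutures(self) -> Iterator[tuple[ParticipantRecord, SutureAnnotation]]:
        for p in self.participants:
            for suture in self.annotations[p.participant_id]:
                yield p, suture

    def iter_segments(
        self,
    ) -> Iterator[tuple[ParticipantRecord, SutureAnnotation, SegmentAnnotation]]:
        for p, suture in self.iter_sutures():
            for seg in suture.segments:
                yield p, suture, seg


# ---------------------------------------------------------------------------
# file format
# ---------------------------------------------------------------------------


def _normalise_token(value: str, column: str, allowed: tuple[str, ...], lineno: int) -> str:
    token = value.strip()
    if column == "action":
        token = _ACTION_ALIASES.get(token, token)
    if token not in allowed:
        raise AnnotationError(
            f"line {lineno}: unknown {column} token {value!r} (allowed: {', '.join(allowed)})"
        )
    return token


def _read_rows(source: Union[str, Path, TextIO]) -> tuple[str, list[tuple[int, list[str]]]]:
    """Return the delimiter and (line number, fields) for every data row."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    numbered = [
        (i + 1, line)
        for i, line in enumerate(text.splitlines())
        if line.strip() and not line.lstrip().startswith("#")
    ]
    if not numbered:
        raise AnnotationError("empty annotation file (no header)")
    header_no, header_line = numbered[0]
    delim = "\t" if "\t" in header_line else ","
    header = next(csv.reader([header_line], delimiter=delim))
    if tuple(h.strip() for h in header) != ANNOTATION_COLUMNS:
        raise AnnotationError(
            f"line {header_no}: header must be exactly {','.join(ANNOTATION_COLUMNS)}"
        )
    rows = []
    for lineno, line in numbered[1:]:
        fields = next(csv.reader([line], delimiter=delim))
        if len(fields) != len(ANNOTATION_COLUMNS):
            raise AnnotationError(
                f"line {lineno}: expected {len(ANNOTATION_COLUMNS)} fields, got {len(fields)}"
            )
        rows.append((lineno, [f.strip() for f in fields]))
    return delim, rows


def read_annotations(source: Union[str, Path, TextIO]) -> AnnotationDataset:
    """Parse and validate an annotation file (comma- or tab-delimited, auto-detected).

    Rows may appear in any order; within each (participant, suture, segment,
    hand) they are normalised to start-time order before validation.  Every
    violation is reported with the offending line number.
    """
    _, rows = _read_rows(source)
    participants: dict[str, ParticipantRecord] = {}
    # (pid, suture, segment) -> hand -> list of (lineno, interval)
    cells: dict[tuple[str, int, str], dict[str, list[tuple[int, AnnotatedInterval]]]] = {}
    suture_order: dict[str, list[int]] = {}

    for lineno, fields in rows:
        rec = dict(zip(ANNOTATION_COLUMNS, fields))
        group = _normalise_token(rec["group"], "group", GROUPS, lineno)
        handed = _normalise_token(rec["handedness"], "handedness", HANDS, lineno)
        segment = _normalise_token(rec["segment"], "segment", SEGMENT_TYPES, lineno)
        hand = _normalise_token(rec["hand"], "hand", HANDS, lineno)
        action = _normalise_token(
            rec["action"], "action", ACTIONS + SPECIAL_ACTIONS, lineno
        )
        target = _normalise_token(rec["target"], "target", TARGETS + ("none",), lineno)
        try:
            suture = int(rec["suture"])
            start = float(rec["start_s"])
            end = float(rec["end_s"])
        except ValueError as exc:
            raise AnnotationError(f"line {lineno}: malformed numeric field ({exc})") from None
        try:
            label = ActivityLabel(action=action, target=target)
            interval = AnnotatedInterval(start_s=start, end_s=end, hand=hand, label=label)
        except AnnotationError as exc:
            raise AnnotationError(f"line {lineno}: {exc}") from None

        pid = rec["participant_id"]
        if pid in participants:
            existing = participants[pid]
            if existing.group != group or existing.handedness != handed:
                raise AnnotationError(
                    f"line {lineno}: participant {pid!r} has inconsistent group/handedness"
                )
        else:
            participants[pid] = ParticipantRecord(pid, group, handed)
        cells.setdefault((pid, suture, segment), {}).setdefault(hand, []).append(
            (lineno, interval)
        )
        suture_order.setdefault(pid, [])
        if suture not in suture_order[pid]:
            suture_order[pid].append(suture)

    annotations: dict[str, list[SutureAnnotation]] = {}
    for pid, sutures in suture_order.items():
        built = []
        for suture_idx in sorted(sutures):
            segs = []
            for seg_type in SEGMENT_TYPES:
                cell = cells.get((pid, suture_idx, seg_type))
                if cell is None:
                    continue
                hands: dict[str, tuple[AnnotatedInterval, ...]] = {}
                for hand in HANDS:
                    if hand not in cell:
                        raise AnnotationError(
                            f"participant {pid}, suture {suture_idx}, segment {seg_type}: "
                            f"no rows for the {hand} hand"
                        )
                    items = sorted(cell[hand], key=lambda t: t[1].start_s)
                    seq = tuple(iv for _, iv in items)
                    for (lno_a, a), (lno_b, b) in zip(items, items[1:]):
                        if b.start_s < a.end_s - _TIME_TOL:
                            raise AnnotationError(
                                f"line {lno_b}: interval overlaps the previous interval "
                                f"(line {lno_a}) of the same hand"
                            )
                        if b.start_s > a.end_s + _TIME_TOL:
                            raise AnnotationError(
                                f"line {lno_b}: gap after the previous interval "
                                f"(line {lno_a}); label waiting time idle or not_visible"
                            )
                    hands[hand] = seq
                segs.append(
                    SegmentAnnotation(
                        segment_type=seg_type,
                        intervals_left=hands["left"],
                        intervals_right=hands["right"],
                    )
                )
            built.append(SutureAnnotation(suture_index=suture_idx, segments=tuple(segs)))
        annotations[pid] = built

    return AnnotationDataset(
        participants=tuple(participants[pid] for pid in participants),
        annotations={pid: tuple(s) for pid, s in annotations.items()},
    )


def write_annotations(dataset: AnnotationDataset, sink: Union[str, Path, TextIO]) -> None:
    """Write a dataset to the standard comma-delimited annotation format.

    ``read_annotations(write_annotations(d))`` reproduces ``d`` exactly: float
    times are serialised with ``repr`` round-trip precision.
    """
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(ANNOTATION_COLUMNS)
    for p, suture in dataset.iter_sutures():
        for seg in suture.segments:
            for hand in HANDS:
                for iv in seg.intervals(hand):
                    writer.writerow(
                        [
                            p.participant_id,
                            p.group,
                            p.handedness,
                            suture.suture_index,
                            seg.segment_type,
                            hand,
                            repr(iv.start_s),
                            repr(iv.end_s),
                            iv.label.action,
                            iv.label.target,
                        ]
                    )
    text = buf.getvalue()
    if isinstance(sink, (str, Path)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _coalesce(intervals: list[AnnotatedInterval]) -> list[AnnotatedInterval]:
    out: list[AnnotatedInterval] = []
    for iv in intervals:
        if out and out[-1].label == iv.label:
            out[-1] = replace(out[-1], end_s=iv.end_s)
        else:
            out.append(iv)
    return out


def merge_short_activities(
    intervals: Sequence[AnnotatedInterval], min_duration: float = 0.5
) -> tuple[AnnotatedInterval, ...]:
    """Merge very short activities into the previous activity.

    Any interval shorter than ``min_duration`` is absorbed by its predecessor
    (the predecessor's end time is extended over it); a short *leading*
    interval, having no predecessor, is absorbed by its successor instead.
    Adjacent intervals that end up sharing a label are coalesced.  Total
    covered time is conserved exactly; if the whole sequence is a single
    interval it is returned unchanged regardless of duration.
    """
    out = _coalesce(list(intervals))
    while len(out) > 1:
        idx = next(
            (i for i, iv in enumerate(out) if iv.duration < min_duration - _TIME_TOL), None
        )
        if idx is None:
            break
        short = out.pop(idx)
        if idx > 0:
            out[idx - 1] = replace(out[idx - 1], end_s=short.end_s)
        else:
            out[0] = replace(out[0], start_s=short.start_s)
        out = _coalesce(out)
    return tuple(out)


def preprocess_dataset(
    dataset: AnnotationDataset, min_duration: float = 0.5
) -> AnnotationDataset:
    """Apply :func:`merge_short_activities` to every hand sequence of every segment."""
    new_annotations: dict[str, tuple[SutureAnnotation, ...]] = {}
    for pid, sutures in dataset.annotations.items():
        rebuilt = []
        for suture in sutures:
            segs = tuple(
                SegmentAnnotation(
                    segment_type=seg.segment_type,
                    intervals_left=merge_short_activities(seg.intervals_left, min_duration),
                    intervals_right=merge_short_activities(seg.intervals_right, min_duration),
                )
                for seg in suture.segments
            )
            rebuilt.append(SutureAnnotation(suture_index=suture.suture_index, segments=segs))
        new_annotations[pid] = tuple(rebuilt)
    return AnnotationDataset(participants=dataset.participants, annotations=new_annotations)
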