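"""Activity-duration vectors.

Each suture (or each segment) of one hand becomes a nonnegative vector whose
components are the total seconds spent in each activity of a chosen
vocabulary, normalised to unit Euclidean length.  Because of the
normalisation the vectors encode the *proportional allocation of time* across
activities, not the speed of the performance: uniformly rescaling all
durations leaves every vector unchanged.

Three vocabulary variants are supported:

``full18``
    the 16 action-by-target labels (actions major, canonical order) followed
    by ``idle`` and ``not_visible``;
``actions_special6``
    targets collapsed: ``move, transport, hold_still, grasp, not_visible,
    idle``;
``actions_only4``
    the four actions only; idle and not-visible time is dropped before
    normalisation, so a stretch consisting solely of nonproductive time has
    no vector (an explicit error / skip).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_model import (
    ACTIONS,
    HANDS,
    AnnotatedInterval,
    AnnotationDataset,
    ActivityLabel,
    all_labels,
)

__all__ = [
    "VOCABULARY_VARIANTS",
    "VectorizationError",
    "ActivityVocabulary",
    "get_vocabulary",
    "ActivityVector",
    "accumulate_durations",
    "unit_normalize",
    "build_vectors",
    "vectors_to_frame",
]

VOCABULARY_VARIANTS = ("full18", "actions_special6", "actions_only4")

_NORM_TOL = 1e-9


class VectorizationError(ValueError):
    """Raised for vectors that cannot be built (e.g. no in-vocabulary time)."""


@dataclass(frozen=True)
class ActivityVocabulary:
    """An ordered activity label list defining the vector basis."""

    variant: str
    labels: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label_key: str) -> int:
        return self.labels.index(label_key)

    def project(self, label: ActivityLabel) -> Optional[str]:
        """Map a full activity label onto this vocabulary; None if out of vocabulary."""
        if self.variant == "full18":
            return label.key
        if self.variant == "actions_special6":
            return label.action
        if self.variant == "actions_only4":
            return label.action if label.is_productive else None
        raise VectorizationError(f"unknown vocabulary variant {self.variant!r}")


def get_vocabulary(variant: str = "full18") -> ActivityVocabulary:
    if variant == "full18":
        labels = tuple(lab.key for lab in all_labels())
    elif variant == "actions_special6":
        labels = ACTIONS + ("not_visible", "idle")
    elif variant == "actions_only4":
        labels = ACTIONS
    else:
        raise VectorizationError(
            f"unknown vocabulary variant {variant!r} (choose from {VOCABULARY_VARIANTS})"
        )
    return ActivityVocabulary(variant=variant, labels=labels)


@dataclass(frozen=True)
class ActivityVector:
    """A unit-length activity-duration vector with its provenance metadata."""

    components: np.ndarray
    vocabulary: ActivityVocabulary
    level: str  # "suture" or "segment"
    hand: str
    participant_id: str
    group: str
    suture_index: int
    segment_type: Optional[str] = None

    def __post_init__(self) -> None:
        comp = np.asarray(self.components, dtype=float)
        object.__setattr__(self, "components", comp)
        if comp.shape != (len(self.vocabulary),):
            raise VectorizationError(
                f"component length {comp.shape} does not match vocabulary "
                f"({len(self.vocabulary)} labels)"
            )
        if (comp < -_NORM_TOL).any():
            raise VectorizationError("activity vector has negative components")
        if abs(float(np.linalg.norm(comp)) - 1.0) > 1e-6:
            raise VectorizationError("activity vector is not unit length")
        if (self.level == "segment") != (self.segment_type is not None):
            raise VectorizationError("segment_type must be present iff level='segment'")


def accumulate_durations(
    intervals: Iterable[AnnotatedInterval], vocabulary: ActivityVocabulary
) -> np.ndarray:
    """Total seconds per vocabulary label; out-of-vocabulary labels contribute nothing."""
    raw = np.zeros(len(vocabulary))
    index = {key: i for i, key in enumerate(vocabulary.labels)}
    for iv in intervals:
        key = vocabulary.project(iv.label)
        if key is not None:
            raw[index[key]] += iv.duration
    return raw


def unit_normalize(raw: np.ndarray) -> np.ndarray:
    """Scale a nonnegative duration vector to unit Euclidean length."""
    raw = np.asarray(raw, dtype=float)
    norm = float(np.linalg.norm(raw))
    if norm <= _NORM_TOL:
        raise VectorizationError(
            "no in-vocabulary activity time: cannot normalise an all-zero duration vector"
        )
    return raw / norm


def build_vectors(
    dataset: AnnotationDataset,
    level: str,
    hand: str,
    vocabulary: ActivityVocabulary,
) -> tuple[list[ActivityVector], list[dict]]:
    """One vector per (participant, suture[, segment]) for one hand.

    Suture-level vectors pool the suture's segment durations before
    normalisation.  Items with zero in-vocabulary time (possible under
    ``actions_only4``) are skipped and reported in the second return value.
    """
    if level not in ("suture", "segment"):
        raise VectorizationError(f"level must be 'suture' or 'segment', got {level!r}")
    if hand not in HANDS:
        raise VectorizationError(f"unknown hand {hand!r}")
    vectors: list[ActivityVector] = []
    skipped: list[dict] = []
    for participant, suture in dataset.iter_sutures():
        units: list[tuple[Optional[str], list[AnnotatedInterval]]]
        if level == "suture":
            pooled = [iv for seg in suture.segments for iv in seg.intervals(hand)]
            units = [(None, pooled)]
        else:
            units = [(seg.segment_type, list(seg.intervals(hand))) for seg in suture.segments]
        for segment_type, intervals in units:
            raw = accumulate_durations(intervals, vocabulary)
            meta = {
                "participant_id": participant.participant_id,
                "group": participant.group,
                "suture_index": suture.suture_index,
                "segment_type": segment_type,
                "hand": hand,
                "level": level,
            }
            try:
                comp = unit_normalize(raw)
            except VectorizationError as exc:
                skipped.append({**meta, "reason": str(exc)})
                continue
            vectors.append(
                ActivityVector(
                    components=comp,
                    vocabulary=vocabulary,
                    level=level,
                    hand=hand,
                    participant_id=participant.participant_id,
                    group=participant.group,
                    suture_index=suture.suture_index,
                    segment_type=segment_type,
                )
            )
    return vectors, skipped


def vectors_to_frame(vectors: Sequence[ActivityVector]) -> pd.DataFrame:
    """Wide table: metadata columns plus one column per vocabulary label."""
    if not vectors:
        return pd.DataFrame()
    vocab = vectors[0].vocabulary
    rows = []
    for v in vectors:
        if v.vocabulary != vocab:
            raise VectorizationError("cannot tabulate vectors from different vocabularies")
        row = {
            "participant_id": v.participant_id,
            "group": v.group,
            "suture_index": v.suture_index,
            "segment_type": v.segment_type,
            "hand": v.hand,
            "level": v.level,
            "vocabulary": vocab.variant,
        }
        row.update(dict(zip(vocab.labels, v.components)))
        rows.append(row)
    return pd.DataFrame(rows)
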