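"""Cosine-similarity scoring of movement patterns against the two skill groups.

Because activity vectors are unit length and nonnegative, the cosine
similarity of two vectors is simply their dot product and lies in [0, 1].
Each suture (or segment) is scored by its mean similarity to every expert
vector and to every novice vector in the cohort, always excluding vectors
from the scored participant's own sutures.  The difference

    difference = mean_expert_sim - mean_novice_sim

is the skill score: positive values mean the performance resembles experts,
negative values mean it resembles novices.  Segment-level scores compare only
segments of the same type (knot1 against knot1, and so on), so that phase
differences are not conflated with skill differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation_model import AnnotationDataset
from .vectorization import ActivityVector, ActivityVocabulary, build_vectors

__all__ = [
    "SimilarityError",
    "SimilarityScore",
    "cosine_similarity",
    "group_similarity",
    "similarity_table",
    "SIMILARITY_COLUMNS",
]

SIMILARITY_COLUMNS = (
    "participant_id",
    "group",
    "suture_index",
    "segment_type",
    "level",
    "hand",
    "vocabulary",
    "mean_expert_sim",
    "mean_novice_sim",
    "difference",
)


class SimilarityError(ValueError):
    """Raised for incomparable vectors or empty comparison pools."""


def _check_comparable(v1: ActivityVector, v2: ActivityVector) -> None:
    if v1.vocabulary != v2.vocabulary:
        raise SimilarityError("vectors use different vocabularies")
    if v1.level != v2.level:
        raise SimilarityError(f"vectors are at different levels ({v1.level} vs {v2.level})")
    if v1.hand != v2.hand:
        raise SimilarityError(f"vectors are for different hands ({v1.hand} vs {v2.hand})")


def cosine_similarity(v1: ActivityVector, v2: ActivityVector) -> float:
    """Dot product of two unit activity vectors; in [0, 1] for nonnegative vectors."""
    _check_comparable(v1, v2)
    return float(np.dot(v1.components, v2.components))


@dataclass(frozen=True)
class SimilarityScore:
    mean_expert_sim: float
    mean_novice_sim: float
    difference: float
    level: str
    hand: str
    participant_id: str
    group: str
    suture_index: int
    segment_type: Optional[str] = None


def group_similarity(
    target_vector: ActivityVector, pool: Sequence[ActivityVector]
) -> SimilarityScore:
    """Mean similarity of one vector to the expert and novice vectors of a pool.

    Vectors belonging to the target's own participant are excluded from both
    means.  At segment level the pool is restricted to vectors of the target's
    segment type.  An empty eligible pool for either group is an error.
    """
    sims: dict[str, list[float]] = {"expert": [], "novice": []}
    for other in pool:
        if other.participant_id == target_vector.participant_id:
            continue
        if (
            target_vector.level == "segment"
            and other.segment_type != target_vector.segment_type
        ):
            continue
        sims[other.group].append(cosine_similarity(target_vector, other))
    for group_name, values in sims.items():
        if not values:
            raise SimilarityError(
                f"no eligible {group_name} vectors after excluding participant "
                f"{target_vector.participant_id!r}"
            )
    mean_expert = float(np.mean(sims["expert"]))
    mean_novice = float(np.mean(sims["novice"]))
    return SimilarityScore(
        mean_expert_sim=mean_expert,
        mean_novice_sim=mean_novice,
        difference=mean_expert - mean_novice,
        level=target_vector.level,
        hand=target_vector.hand,
        participant_id=target_vector.participant_id,
        group=target_vector.group,
        suture_index=target_vector.suture_index,
        segment_type=target_vector.segment_type,
    )


def similarity_table(
    dataset: AnnotationDataset,
    level: str,
    hand: str,
    vocabulary: ActivityVocabulary,
) -> pd.DataFrame:
    """Score every suture (or segment) of one hand against both groups.

    Returns one row per activity vector with the columns in
    :data:`SIMILARITY_COLUMNS`.  Deterministic given the dataset.
    """
    vectors, skipped = build_vectors(dataset, level=level, hand=hand, vocabulary=vocabulary)
    rows = []
    for v in vectors:
        try:
            score = group_similarity(v, vectors)
        except SimilarityError as exc:
            raise SimilarityError(
                f"participant {v.participant_id}, suture {v.suture_index}"
                + (f", segment {v.segment_type}" if v.segment_type else "")
                + f": {exc}"
            ) from None
        rows.append(
            {
                "participant_id": score.participant_id,
                "group": score.group,
                "suture_index": score.suture_index,
                "segment_type": score.segment_type,
                "level": score.level,
                "hand": score.hand,
                "vocabulary": vocabulary.variant,
                "mean_expert_sim": score.mean_expert_sim,
                "mean_novice_sim": score.mean_novice_sim,
                "difference": score.difference,
            }
        )
    frame = pd.DataFrame(rows, columns=list(SIMILARITY_COLUMNS))
    frame.attrs["skipped"] = skipped
    return frame
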