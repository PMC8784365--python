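import pytest
from hypothesis import HealthCheck, settings

from suturespm.annotation_model import (
    ActivityLabel,
    AnnotatedInterval,
    AnnotationDataset,
    ParticipantRecord,
    SegmentAnnotation,
    SutureAnnotation,
    preprocess_dataset,
)
from suturespm.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_intervals(hand, specs, t0=0.0):
    """Build a contiguous interval sequence from (duration, label_key) pairs."""
    out = []
    t = t0
    for dur, key in specs:
        out.append(
            AnnotatedInterval(
                start_s=t, end_s=t + dur, hand=hand, label=ActivityLabel.from_key(key)
            )
        )
        t += dur
    return tuple(out)


def make_segment(segment_type, left_specs, right_specs, t0=0.0):
    """Segment whose hands are built from (duration, label_key) lists.

    Both hands must cover the same total duration.
    """
    return SegmentAnnotation(
        segment_type=segment_type,
        intervals_left=make_intervals("left", left_specs, t0),
        intervals_right=make_intervals("right", right_specs, t0),
    )


def make_dataset(participant_specs):
    """Dataset from {pid: (group, [suture -> [segment specs]])}.

    Each suture is a list of (segment_type, left_specs, right_specs).
    """
    participants = []
    annotations = {}
    for pid, (group, sutures) in participant_specs.items():
        participants.append(ParticipantRecord(pid, group))
        built = []
        for s_idx, segments in enumerate(sutures, start=1):
            t0 = 0.0
            segs = []
            for seg_type, left_specs, right_specs in segments:
                seg = make_segment(seg_type, left_specs, right_specs, t0)
                segs.append(seg)
                t0 = seg.end_s
            built.append(SutureAnnotation(suture_index=s_idx, segments=tuple(segs)))
        annotations[pid] = tuple(built)
    return AnnotationDataset(participants=tuple(participants), annotations=annotations)


@pytest.fixture(scope="session")
def paper_cohort():
    """Default study-shaped synthetic cohort (5+5 participants x 5 sutures), merged."""
    return preprocess_dataset(generate_dataset(SyntheticConfig(seed=11)))


@pytest.fixture(scope="session")
def small_cohort():
    """Small 2+2 cohort with two segment types, for cheap structural tests."""
    config = SyntheticConfig(
        seed=7,
        n_experts=2,
        n_novices=2,
        sutures_per_participant=2,
        segments=("needle_transport", "piercing"),
    )
    return preprocess_dataset(generate_dataset(config))
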