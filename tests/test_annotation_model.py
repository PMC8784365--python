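import io

import pytest
from hypothesis import given, strategies as st

from suturespm.annotation_model import (
    AnnotationDataset,
    AnnotationError,
    ActivityLabel,
    all_labels,
    merge_short_activities,
    read_annotations,
    write_annotations,
)
from suturespm.synthetic import SyntheticConfig, generate_dataset

from conftest import make_intervals

HEADER = "participant_id,group,handedness,suture,segment,hand,start_s,end_s,action,target"


def _file(*rows):
    return io.StringIO("\n".join([HEADER, *rows]) + "\n")


class TestActivityLabel:
    def test_vocabulary_has_18_labels_16_with_targets(self):
        labels = all_labels()
        assert len(labels) == 18
        assert len(set(labels)) == 18
        assert sum(lab.is_productive for lab in labels) == 16

    @pytest.mark.parametrize(
        "action,target",
        [("idle", "incision"), ("not_visible", "needle"), ("grasp", "none"), ("bogus", "needle")],
    )
    def test_invalid_label_combinations_rejected(self, action, target):
        with pytest.raises(AnnotationError):
            ActivityLabel(action=action, target=target)

    def test_key_round_trip(self):
        for lab in all_labels():
            assert ActivityLabel.from_key(lab.key) == lab


class TestReadAnnotations:
    def test_minimal_valid_file(self):
        ds = read_annotations(
            _file(
                "p1,novice,right,1,needle_transport,left,0,5.0,idle,none",
                "p1,novice,right,1,needle_transport,right,0,5.0,transport,needle",
            )
        )
        assert len(ds.participants) == 1
        assert ds.n_sutures == 1
        seg = ds.annotations["p1"][0].segments[0]
        assert seg.intervals_right[0].label.key == "transport;needle"
        assert seg.duration == pytest.approx(5.0)

    def test_tab_delimited_autodetected(self):
        text = "\n".join(
            [
                HEADER.replace(",", "\t"),
                "p1\tnovice\tright\t1\tpiercing\tleft\t0\t5\tidle\tnone",
                "p1\tnovice\tright\t1\tpiercing\tright\t0\t5\tmove\tneedle",
            ]
        )
        ds = read_annotations(io.StringIO(text))
        assert ds.annotations["p1"][0].segments[0].segment_type == "piercing"

    def test_grab_accepted_as_grasp_alias(self):
        ds = read_annotations(
            _file(
                "p1,expert,right,1,needle_transport,left,0,5,grab,tool",
                "p1,expert,right,1,needle_transport,right,0,5,idle,none",
            )
        )
        assert ds.annotations["p1"][0].segments[0].intervals_left[0].label.action == "grasp"

    def test_rows_normalised_to_start_order(self):
        ds = read_annotations(
            _file(
                "p1,novice,right,1,needle_transport,left,3,6,idle,none",
                "p1,novice,right,1,needle_transport,left,0,3,move,needle",
                "p1,novice,right,1,needle_transport,right,0,6,hold_still,incision",
            )
        )
        starts = [iv.start_s for iv in ds.annotations["p1"][0].segments[0].intervals_left]
        assert starts == [0.0, 3.0]

    @pytest.mark.parametrize(
        "rows,fragment",
        [
            # special label carrying a target
            (["p1,novice,right,1,piercing,left,0,5,idle,incision",
              "p1,novice,right,1,piercing,right,0,5,move,needle"], "line 2"),
            # overlapping intervals within one hand
            (["p1,novice,right,1,piercing,left,0,5,move,needle",
              "p1,novice,right,1,piercing,left,4,9,idle,none",
              "p1,novice,right,1,piercing,right,0,9,move,needle"], "overlap"),
            # gap within one hand
            (["p1,novice,right,1,piercing,left,0,4,move,needle",
              "p1,novice,right,1,piercing,left,5,9,idle,none",
              "p1,novice,right,1,piercing,right,0,9,move,needle"], "gap"),
            # unknown action token
            (["p1,novice,right,1,piercing,left,0,5,fly,needle",
              "p1,novice,right,1,piercing,right,0,5,move,needle"], "unknown action"),
            # productive action without a target
            (["p1,novice,right,1,piercing,left,0,5,move,none",
              "p1,novice,right,1,piercing,right,0,5,idle,none"], "target"),
            # one hand missing entirely
            (["p1,novice,right,1,piercing,left,0,5,move,needle"], "right hand"),
            # end before start
            (["p1,novice,right,1,piercing,left,5,2,move,needle",
              "p1,novice,right,1,piercing,right,0,5,idle,none"], "duration"),
        ],
    )
    def test_validation_errors_carry_context(self, rows, fragment):
        with pytest.raises(AnnotationError, match=fragment):
            read_annotations(_file(*rows))

    def test_bad_header_rejected(self):
        with pytest.raises(AnnotationError, match="header"):
            read_annotations(io.StringIO("a,b,c\n"))

    def test_comment_lines_ignored(self):
        ds = read_annotations(
            _file(
                "# a comment",
                "p1,novice,right,1,needle_transport,left,0,5,idle,none",
                "p1,novice,right,1,needle_transport,right,0,5,move,needle",
            )
        )
        assert ds.n_sutures == 1


class TestWriteAnnotations:
    def test_empty_dataset_writes_header_only(self):
        buf = io.StringIO()
        write_annotations(AnnotationDataset(participants=(), annotations={}), buf)
        assert buf.getvalue().strip() == HEADER

    def test_row_count_matches_interval_count(self, small_cohort):
        buf = io.StringIO()
        write_annotations(small_cohort, buf)
        n_intervals = sum(
            len(seg.intervals_left) + len(seg.intervals_right)
            for _, _, seg in small_cohort.iter_segments()
        )
        assert buf.getvalue().count("\n") - 1 == n_intervals

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_round_trip_identity(self, seed):
        config = SyntheticConfig(
            seed=seed, n_experts=1, n_novices=1, sutures_per_participant=1,
            segments=("needle_transport", "piercing"),
        )
        dataset = generate_dataset(config)
        buf = io.StringIO()
        write_annotations(dataset, buf)
        assert read_annotations(io.StringIO(buf.getvalue())) == dataset


class TestMergeShortActivities:
    @pytest.mark.parametrize(
        "specs,expected",
        [
            # short middle interval absorbed by predecessor, then coalesced
            ([(2.0, "move;needle"), (0.3, "grasp;thread"), (1.0, "move;needle")],
             [(3.3, "move;needle")]),
            # short leading interval absorbed by successor
            ([(0.2, "grasp;thread"), (5.0, "move;needle")], [(5.2, "move;needle")]),
            # nothing below threshold: unchanged
            ([(0.6, "move;needle"), (1.0, "idle"), (2.0, "grasp;thread")],
             [(0.6, "move;needle"), (1.0, "idle"), (2.0, "grasp;thread")]),
            # adjacent equal labels coalesce even without short intervals
            ([(1.0, "idle"), (2.0, "idle")], [(3.0, "idle")]),
            # cascade: two shorts in a row
            ([(3.0, "idle"), (0.2, "move;needle"), (0.2, "grasp;thread"), (4.0, "idle")],
             [(7.4, "idle")]),
        ],
    )
    def test_examples(self, specs, expected):
        merged = merge_short_activities(make_intervals("left", specs))
        got = [(pytest.approx(iv.duration, abs=1e-9), iv.label.key) for iv in merged]
        assert got == expected

    def test_single_short_interval_survives(self):
        (only,) = merge_short_activities(make_intervals("left", [(0.2, "idle")]))
        assert only.duration == pytest.approx(0.2)

    def test_empty_sequence(self):
        assert merge_short_activities(()) == ()

    @given(
        durations=st.lists(st.floats(min_value=0.05, max_value=5.0), min_size=1, max_size=30),
        label_idx=st.lists(st.integers(min_value=0, max_value=17), min_size=30, max_size=30),
    )
    def test_conservation_and_threshold(self, durations, label_idx):
        labels = all_labels()
        specs = [
            (d, labels[label_idx[i]].key) for i, d in enumerate(durations)
        ]
        intervals = make_intervals("right", specs)
        merged = merge_short_activities(intervals)
        # total time conserved
        assert sum(iv.duration for iv in merged) == pytest.approx(
            sum(durations), abs=1e-9
        )
        # span endpoints preserved
        assert merged[0].start_s == pytest.approx(intervals[0].start_s)
        assert merged[-1].end_s == pytest.approx(intervals[-1].end_s, abs=1e-9)
        # no sub-threshold interval unless the whole thing collapsed to one
        if len(merged) > 1:
            assert all(iv.duration >= 0.5 - 1e-9 for iv in merged)
        # adjacent labels differ after coalescing
        assert all(a.label != b.label for a, b in zip(merged, merged[1:]))
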