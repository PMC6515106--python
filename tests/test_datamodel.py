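import numpy as np
import pytest

from cycleannot.datamodel import (
    BoundaryEvent,
    FormatError,
    InvalidTrackError,
    LabelTrack,
    Segment,
    TaskWindow,
    TimeSeries,
    boundaries_to_track,
    fill_gaps,
    read_labels,
    read_signals,
    read_tasks,
    track_to_boundaries,
    write_labels,
    write_signals,
    write_tasks,
)
from cycleannot.synthio import SubjectScenario, generate_subject


def walk(a, b, phase, foot="left"):
    return Segment(a, b, "walk", phase, foot)


class TestSegment:
    def test_end_must_exceed_start(self):
        with pytest.raises(ValueError):
            Segment(1.0, 1.0, "walk", "swing")

    def test_phaseless_activities_reject_phases(self):
        with pytest.raises(ValueError):
            Segment(0, 1, "rest", "swing")
        with pytest.raises(ValueError):
            Segment(0, 1, "cycle", "stance")

    def test_cyclic_activities_require_phase(self):
        with pytest.raises(ValueError):
            Segment(0, 1, "walk", "none")

    def test_unknown_enum_values(self):
        with pytest.raises(ValueError):
            Segment(0, 1, "moonwalk", "swing")
        with pytest.raises(ValueError):
            Segment(0, 1, "walk", "swing", foot="middle")


class TestTrackValidation:
    def test_overlap_rejected(self):
        track = LabelTrack("left", [walk(0, 1, "swing"), walk(0.5, 2, "stance")])
        with pytest.raises(InvalidTrackError):
            track.check_sorted()

    def test_unsorted_rejected(self):
        track = LabelTrack("left", [walk(2, 3, "swing"), walk(0, 1, "stance")])
        with pytest.raises(InvalidTrackError):
            track.check_sorted()

    def test_alternation_enforced(self):
        track = LabelTrack("left", [walk(0, 1, "swing"), walk(1, 2, "swing")])
        with pytest.raises(InvalidTrackError):
            track.validate()

    def test_bout_must_start_and_end_with_swing(self):
        track = LabelTrack(
            "left", [walk(0, 1, "stance"), walk(1, 2, "swing")]
        )
        with pytest.raises(InvalidTrackError):
            track.validate()

    def test_compliant_bout_passes(self):
        track = LabelTrack(
            "left",
            [walk(0, 1, "swing"), walk(1, 2, "stance"), walk(2, 3, "swing")],
        )
        track.validate()

    def test_transition_separator_stance_allowed(self):
        segs = [
            walk(0, 1, "swing"),
            walk(1, 2, "stance"),
            walk(2, 3, "swing"),
            Segment(3, 3.5, "jog", "stance"),
            Segment(3.5, 4, "jog", "swing"),
        ]
        # jog bout starts with stance but adjoins the walk bout: separator
        LabelTrack("left", segs).validate()


class TestBoundaries:
    def test_three_contiguous_segments_give_four_events(self):
        track = LabelTrack(
            "left",
            [walk(0, 1, "swing"), walk(1, 2, "stance"), walk(2, 3, "swing")],
        )
        events = track_to_boundaries(track)
        assert len(events) == 4
        assert [e.time_s for e in events] == [0, 1, 2, 3]
        assert events[0].left_label is None
        assert events[0].right_label == ("walk", "swing")
        assert events[-1].right_label is None

    def test_empty_track(self):
        assert track_to_boundaries(LabelTrack("left", [])) == []

    def test_gap_boundaries_match_endpoint_enumeration(self):
        # oracle: brute-force scan of all segment endpoints, deduped
        track = LabelTrack(
            "left",
            [walk(0, 1, "swing"), walk(1.5, 2.5, "stance"), walk(2.5, 3, "swing")],
        )
        endpoints = sorted({s.start_s for s in track} | {s.end_s for s in track})
        events = track_to_boundaries(track)
        assert [e.time_s for e in events] == endpoints
        gap_open = next(e for e in events if e.time_s == 1)
        assert gap_open.right_label is None  # nothing starts at the gap opening
        gap_close = next(e for e in events if e.time_s == 1.5)
        assert gap_close.left_label is None

    def test_invalid_track_rejected(self):
        track = LabelTrack("left", [walk(0, 2, "swing"), walk(1, 3, "stance")])
        with pytest.raises(InvalidTrackError):
            track_to_boundaries(track)

    def test_boundaries_roundtrip_on_contiguous_track(self):
        track = LabelTrack(
            "left",
            [
                Segment(0, 3, "rest", "none"),
                walk(3, 4, "swing"),
                walk(4, 5, "stance"),
                walk(5, 6, "swing"),
            ],
        )
        rebuilt = boundaries_to_track(track_to_boundaries(track), foot="left")
        assert rebuilt.segments == track.segments


class TestFillAndCrop:
    def test_fill_gaps_tiles_interval(self):
        track = LabelTrack("left", [walk(1, 2, "swing")])
        filled = fill_gaps(track, 0.0, 3.0)
        assert [s.activity for s in filled] == ["rest", "walk", "rest"]
        assert filled.segments[0].start_s == 0.0
        assert filled.segments[-1].end_s == 3.0


class TestSignalIO:
    def test_csv_roundtrip(self, tmp_path, rng):
        series = TimeSeries(["GZ", "AX"], rng.standard_normal((50, 2)), 200.0, 0.25)
        path = tmp_path / "sig.csv"
        write_signals(series, path)
        back = read_signals(path)
        assert back.channel_names == ["GZ", "AX"]
        assert back.rate_hz == 200.0
        assert back.t0_s == 0.25
        np.testing.assert_allclose(back.samples, series.samples, rtol=0, atol=1e-12)

    def test_hdf5_roundtrip(self, tmp_path, rng):
        series = TimeSeries(["a"], rng.standard_normal((10, 1)), 100.0)
        path = tmp_path / "sig.h5"
        write_signals(series, path)
        back = read_signals(path)
        np.testing.assert_array_equal(back.samples, series.samples)
        assert back.rate_hz == 100.0

    def test_missing_rate_metadata_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("GZ,AX\n0.0,0.1\n")
        with pytest.raises(FormatError):
            read_signals(path)

    def test_ragged_rows_rejected(self, tmp_path):
        path = tmp_path / "ragged.csv"
        path.write_text("# rate_hz=200\nGZ,AX\n0.0,0.1\n0.5\n")
        with pytest.raises(FormatError):
            read_signals(path)

    def test_zero_frame_roundtrip(self, tmp_path):
        series = TimeSeries(["GZ"], np.empty((0, 1)), 200.0)
        path = tmp_path / "empty.csv"
        write_signals(series, path)
        back = read_signals(path)
        assert back.n_frames == 0
        assert back.rate_hz == 200.0


class TestLabelIO:
    def test_two_segment_roundtrip(self, tmp_path):
        track = LabelTrack("left", [walk(0, 1, "swing"), walk(1, 2, "stance")])
        path = tmp_path / "labels.csv"
        write_labels(track, path)
        assert read_labels(path).segments == track.segments

    def test_json_roundtrip(self, tmp_path):
        track = LabelTrack("right", [Segment(0, 2, "rest", foot="right")])
        path = tmp_path / "labels.json"
        write_labels(track, path)
        back = read_labels(path)
        assert back.foot == "right"
        assert back.segments == track.segments

    def test_end_before_start_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("start_s,end_s,activity,phase,foot\n2.0,1.0,walk,swing,left\n")
        with pytest.raises(FormatError):
            read_labels(path)

    def test_unknown_activity_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("start_s,end_s,activity,phase,foot\n0.0,1.0,moonwalk,swing,left\n")
        with pytest.raises(FormatError):
            read_labels(path)

    def test_large_synthetic_track_roundtrip(self, tmp_path):
        # ~1000 segments from the generator, field-by-field equality
        bundle = generate_subject(
            SubjectScenario(seed=11, bouts=[("walk", 260, 2.0), ("jog", 260, 2.0)])
        )
        track = bundle.truth["left"]
        assert len(track) > 1000
        path = tmp_path / "big.csv"
        write_labels(track, path)
        back = read_labels(path)
        assert len(back) == len(track)
        for a, b in zip(back.segments, track.segments):
            assert a == b


class TestTasks:
    def test_allowed_activities_nonempty(self):
        with pytest.raises(ValueError):
            TaskWindow(0, 1, "t", frozenset())

    def test_roundtrip(self, tmp_path):
        tasks = [
            TaskWindow(0, 10, "t0", frozenset({"walk", "rest"})),
            TaskWindow(10, 20, "t1", frozenset({"cycle", "rest"})),
        ]
        path = tmp_path / "tasks.csv"
        write_tasks(tasks, path)
        back = read_tasks(path)
        assert [t.allowed_activities for t in back] == [t.allowed_activities for t in tasks]
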