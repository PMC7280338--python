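"""Annotation streams: editing semantics, sources, classifiers, persistence."""

import copy
import json

import numpy as np
import pytest

from weargaze import events as ev
from weargaze.errors import (
    AnnotationError,
    CategoryError,
    ConfigError,
    EventFileFormatError,
    FlagError,
    LockedStreamError,
    NoOpError,
    OverlapError,
    ParseError,
    RangeError,
    StreamValidationError,
)
from weargaze.recording_model import TtlEvent
from weargaze.stream_assembly import parse_recording
from weargaze.synth import ScanpathScript, fixation, gap, generate_recording, saccade


FIX_SACC = (
    ev.Category("fixation"),
    ev.Category("saccade", ("vergence",)),
)


def _stream(annotations=()):
    return ev.EventStream(name="coding", categories=FIX_SACC, annotations=annotations)


class TestAddAnnotation:
    def test_empty_stream_click_spans_from_zero(self):
        s = ev.add_annotation(_stream(), 2.0, "fixation")
        assert s.annotations == (ev.Annotation(0.0, 2.0, "fixation"),)

    def test_spans_from_end_of_previous_annotation(self):
        s = _stream((ev.Annotation(0.0, 1.0, "fixation"),))
        s = ev.add_annotation(s, 3.0, "saccade")
        assert s.annotations[-1] == ev.Annotation(1.0, 3.0, "saccade")

    def test_click_inside_existing_is_overlap_error(self):
        s = _stream((ev.Annotation(0.0, 1.0, "fixation"),))
        with pytest.raises(OverlapError):
            ev.add_annotation(s, 0.5, "saccade")

    def test_unknown_label_rejected(self):
        with pytest.raises(CategoryError):
            ev.add_annotation(_stream(), 1.0, "blink")

    def test_locked_stream_rejects_edits(self):
        s = ev.EventStream(name="ttl", categories=FIX_SACC, locked=True)
        with pytest.raises(LockedStreamError):
            ev.add_annotation(s, 1.0, "fixation")


class TestSplitRelabelMoveRemove:
    def test_split_preserves_label_and_flags(self):
        s = _stream((ev.Annotation(0.0, 2.0, "saccade", frozenset({"vergence"})),))
        s = ev.split_annotation(s, 1.0)
        assert [a.start for a in s.annotations] == [0.0, 1.0]
        assert all(a.label == "saccade" and "vergence" in a.flags for a in s.annotations)

    def test_split_then_merge_restores_original(self):
        orig = _stream((ev.Annotation(0.0, 2.0, "fixation"),))
        split = ev.split_annotation(orig, 1.0)
        assert ev.merge_adjacent_equal(split).annotations == orig.annotations

    def test_split_on_boundary_is_noop_error(self):
        s = _stream((ev.Annotation(0.0, 2.0, "fixation"),))
        with pytest.raises(NoOpError):
            ev.split_annotation(s, 0.0)

    def test_relabel_with_valid_flag(self):
        s = _stream((ev.Annotation(0.0, 1.0, "fixation"),))
        s = ev.relabel_annotation(s, 0, "saccade", ["vergence"])
        assert s.annotations[0].label == "saccade"
        assert s.annotations[0].flags == {"vergence"}

    def test_relabel_with_invalid_flag_rejected(self):
        s = _stream((ev.Annotation(0.0, 1.0, "saccade"),))
        with pytest.raises(FlagError):
            ev.relabel_annotation(s, 0, "fixation", ["vergence"])

    def test_move_shared_boundary(self):
        s = _stream(
            (ev.Annotation(0.0, 1.0, "fixation"), ev.Annotation(1.0, 2.0, "saccade"))
        )
        s = ev.move_boundary(s, 1, 1.5)
        assert s.annotations[0].end == 1.5
        assert s.annotations[1].start == 1.5

    def test_move_crossing_neighbor_is_range_error(self):
        s = _stream(
            (ev.Annotation(0.0, 1.0, "fixation"), ev.Annotation(1.0, 2.0, "saccade"))
        )
        with pytest.raises(RangeError):
            ev.move_boundary(s, 1, 2.5)

    def test_remove_annotation(self):
        s = _stream(
            (ev.Annotation(0.0, 1.0, "fixation"), ev.Annotation(1.0, 2.0, "saccade"))
        )
        s = ev.remove_annotation(s, 0)
        assert len(s.annotations) == 1
        assert s.annotations[0].label == "saccade"

    def test_duration_conserved_by_split_and_relabel(self):
        s = _stream((ev.Annotation(0.0, 2.0, "fixation"),))
        total = s.total_annotated
        s2 = ev.split_annotation(s, 0.7)
        assert s2.total_annotated == pytest.approx(total)
        s3 = ev.relabel_annotation(s2, 0, "saccade")
        assert s3.total_annotated == pytest.approx(total)


class TestRandomEditSequences:
    def test_invariants_hold_under_many_random_edits(self):
        """10^4 random add/split/relabel/remove/move edits never break the
        stream invariants, and the annotated duration never goes negative
        or past the recording end."""
        rng = np.random.default_rng(123)
        duration = 60.0
        s = _stream()
        applied = 0
        attempts = 0
        while applied < 10_000 and attempts < 60_000:
            attempts += 1
            op = rng.integers(0, 5)
            try:
                if op == 0:
                    s = ev.add_annotation(
                        s, float(rng.uniform(0, duration)),
                        "fixation" if rng.random() < 0.5 else "saccade",
                    )
                elif op == 1 and s.annotations:
                    s = ev.split_annotation(s, float(rng.uniform(0, duration)))
                elif op == 2 and s.annotations:
                    idx = int(rng.integers(0, len(s.annotations)))
                    s = ev.relabel_annotation(s, idx, "saccade", ["vergence"])
                elif op == 3 and s.annotations:
                    s = ev.remove_annotation(s, int(rng.integers(0, len(s.annotations))))
                elif op == 4 and s.annotations:
                    edges = sorted({e for a in s.annotations for e in (a.start, a.end)})
                    s = ev.move_boundary(
                        s, int(rng.integers(0, len(edges))),
                        float(rng.uniform(0, duration)), duration=duration,
                    )
                else:
                    continue
            except AnnotationError:
                continue
            applied += 1
            ev.validate_stream(s, duration=duration)
            assert 0.0 <= s.total_annotated <= duration + 1e-9
        assert applied == 10_000


class TestTtlStream:
    def test_levels_scheme_spans_between_changes(self):
        ttl = [TtlEvent(1.0, 1), TtlEvent(2.0, 0)]
        s = ev.ttl_stream(ttl, scheme="levels", duration=5.0)
        assert s.locked
        assert s.annotations == (
            ev.Annotation(1.0, 2.0, "1"),
            ev.Annotation(2.0, 5.0, "0"),
        )

    def test_edges_scheme_widens_to_one_gaze_interval(self):
        ttl = [TtlEvent(1.0, 1), TtlEvent(2.0, 0)]
        s = ev.ttl_stream(ttl, scheme="edges", duration=5.0, gaze_interval=0.02)
        assert s.annotations[0] == ev.Annotation(1.0, 1.02, "1")

    def test_no_activity_gives_empty_stream(self):
        s = ev.ttl_stream([], duration=5.0)
        assert s.annotations == ()

    def test_button_press_script_yields_one_annotation_per_press(self, tmp_path):
        presses = (1.0, 3.5, 7.25)
        script = ScanpathScript(
            episodes=(fixation(10_000, 0, 0),), ttl_times=presses, seed=40
        )
        res = generate_recording(script, tmp_path)
        recording, _ = parse_recording(res.recording_dir)
        s = ev.ttl_stream(recording.ttl, scheme="levels", duration=recording.duration_s)
        high = [a for a in s.annotations if a.label == "1"]
        assert len(high) == len(presses)
        assert [a.start for a in high] == pytest.approx(list(presses), abs=1e-6)


class TestTextFiles:
    def _write(self, path, rows, header="start_s\tend_s\tlabel\tflags"):
        path.write_text(header + "\n" + "\n".join(rows) + ("\n" if rows else ""))

    def test_valid_file_loads_all_rows(self, tmp_path):
        f = tmp_path / "events.tsv"
        self._write(f, ["0.0\t1.0\tfixation\t", "1.0\t1.2\tsaccade\tvergence",
                        "1.2\t3.0\tfixation\t"])
        s = ev.load_events_from_text(f, FIX_SACC)
        assert len(s.annotations) == 3
        assert s.annotations[1].flags == {"vergence"}
        assert s.source == "file"

    def test_overlapping_rows_are_format_error(self, tmp_path):
        f = tmp_path / "events.tsv"
        self._write(f, ["0.0\t2.0\tfixation\t", "1.0\t3.0\tfixation\t"])
        with pytest.raises(EventFileFormatError, match="overlap"):
            ev.load_events_from_text(f, FIX_SACC)

    def test_unknown_label_is_category_error(self, tmp_path):
        f = tmp_path / "events.tsv"
        self._write(f, ["0.0\t1.0\tblink\t"])
        with pytest.raises(CategoryError):
            ev.load_events_from_text(f, FIX_SACC)

    def test_edit_then_reset_restores_file_contents(self, tmp_path):
        f = tmp_path / "events.tsv"
        self._write(f, ["0.0\t1.0\tfixation\t", "1.0\t1.2\tsaccade\t"])
        s = ev.load_events_from_text(f, FIX_SACC)
        edited = ev.remove_annotation(s, 0)
        assert len(edited.annotations) == 1
        restored = ev.reset_stream(edited)
        assert restored.annotations == s.annotations
        out = tmp_path / "roundtrip.tsv"
        ev.save_events_to_text(restored, out)
        reloaded = ev.load_events_from_text(out, FIX_SACC)
        assert reloaded.annotations == s.annotations


class TestClassifierPlugins:
    def test_unknown_entry_point_is_lookup_error(self, five_fix_recording):
        recording, _, _ = five_fix_recording
        spec = ev.ClassifierSpec(id="x", entry_point="does_not_exist")
        with pytest.raises(ConfigError, match="does_not_exist"):
            ev.run_classifier(recording, spec)

    def test_parameter_out_of_range_is_config_error(self):
        with pytest.raises(ConfigError, match="outside"):
            ev.ClassifierParameter("velocity_threshold_dps", 5000.0, 10.0, 1000.0)

    def test_overlapping_output_names_the_classifier(self, five_fix_recording):
        recording, _, _ = five_fix_recording

        @ev.register_classifier("bad_classifier")
        def bad(recording):
            cats = (ev.Category("a"),)
            s = ev.EventStream(name="bad", categories=cats)
            # bypass construction-time validation to emulate a buggy plugin
            s.annotations = (ev.Annotation(0.0, 2.0, "a"), ev.Annotation(1.0, 3.0, "a"))
            return s

        spec = ev.ClassifierSpec(id="bad_classifier", entry_point="bad_classifier")
        with pytest.raises(StreamValidationError, match="bad_classifier"):
            ev.run_classifier(copy.deepcopy(recording), spec)
        del ev.CLASSIFIER_REGISTRY["bad_classifier"]

    def test_run_classifier_sets_source_and_name(self, five_fix_recording):
        recording, _, _ = five_fix_recording
        s = ev.run_classifier(copy.deepcopy(recording), ev.DEFAULT_SLOW_FAST_SPEC)
        assert s.source == "classifier"
        assert s.name == "slow_fast"

    def test_with_values_rejects_unknown_parameter(self):
        with pytest.raises(ConfigError):
            ev.DEFAULT_SLOW_FAST_SPEC.with_values(nope=1.0)


class TestClassifySlowFast:
    def test_recovers_scripted_episodes(self, five_fix_recording):
        recording, _, res = five_fix_recording
        s = ev.classify_slow_fast(copy.deepcopy(recording))
        truth = res.ground_truth.annotations
        assert len(s.annotations) == len(truth) == 9
        dt = recording.dt
        for got, want in zip(s.annotations, truth):
            assert got.label == want.label
            assert abs(got.start - want.start) <= dt + 1e-9
            assert abs(got.end - want.end) <= dt + 1e-9

    def test_output_covers_full_timeline_without_gaps(self, five_fix_recording):
        recording, _, _ = five_fix_recording
        s = ev.classify_slow_fast(copy.deepcopy(recording))
        assert s.annotations[0].start == 0.0
        assert s.annotations[-1].end == pytest.approx(recording.duration_s)
        for a, b in zip(s.annotations, s.annotations[1:]):
            assert a.end == pytest.approx(b.start)

    def test_constant_zero_velocity_is_one_slow_annotation(self, tmp_path):
        script = ScanpathScript(episodes=(fixation(4000, 0, 0),), noise_sd=0.0, seed=50)
        res = generate_recording(script, tmp_path)
        recording, _ = parse_recording(res.recording_dir)
        s = ev.classify_slow_fast(recording)
        assert [a.label for a in s.annotations] == [ev.SLOW]

    def test_square_wave_velocity_recovers_blocks(self, five_fix_recording):
        """Synthetic alternating 0 / 300 deg/s velocity in 200-ms blocks is
        segmented at the block boundaries to within one sample."""
        recording, _, _ = five_fix_recording
        rec = copy.deepcopy(recording)
        from weargaze.gaze_kinematics import compute_kinematics

        kin = compute_kinematics(rec)
        n = len(rec.gaze)
        block = int(0.2 * rec.rate_hz)
        speed = np.where((np.arange(n) // block) % 2 == 0, 0.0, 300.0)
        kin.velocity.left_speed = speed
        kin.velocity.right_speed = speed
        rec.gaze.binocularity[:] = "binocular"
        s = ev.classify_slow_fast(rec, velocity_threshold_dps=100.0)
        expected_edges = np.arange(block, n, block) * rec.dt
        got_edges = np.array([a.end for a in s.annotations[:-1]])
        assert len(got_edges) == len(expected_edges)
        np.testing.assert_allclose(got_edges, expected_edges, atol=rec.dt + 1e-9)

    def test_one_sample_blip_kept_when_sample_exceeds_min_duration(self, tmp_path):
        # at 50 Hz one sample lasts 20 ms >= min_fast_ms = 10 ms: blip survives
        script = ScanpathScript(episodes=(fixation(4000, 0, 0),), noise_sd=0.0, seed=51)
        res = generate_recording(script, tmp_path)
        recording, _ = parse_recording(res.recording_dir)
        from weargaze.gaze_kinematics import compute_kinematics

        kin = compute_kinematics(recording)
        speed = np.zeros(len(recording.gaze))
        speed[100] = 500.0
        kin.velocity.left_speed = speed
        kin.velocity.right_speed = speed
        s = ev.classify_slow_fast(recording, min_fast_ms=10.0)
        fast = [a for a in s.annotations if a.label == ev.FAST]
        assert len(fast) == 1
        assert fast[0].duration == pytest.approx(recording.dt)

    def test_all_missing_recording_is_single_missing_annotation(self, five_fix_recording):
        recording, _, _ = five_fix_recording
        rec = copy.deepcopy(recording)
        rec.gaze.binocularity[:] = "missing"
        for eye in ("left", "right"):
            getattr(rec.gaze, f"{eye}_azimuth")[:] = np.nan
            getattr(rec.gaze, f"{eye}_elevation")[:] = np.nan
        rec.derived = None
        s = ev.classify_slow_fast(rec)
        assert [a.label for a in s.annotations] == [ev.GAP]

    def test_deterministic_across_runs(self, five_fix_recording):
        recording, _, _ = five_fix_recording
        s1 = ev.classify_slow_fast(copy.deepcopy(recording))
        s2 = ev.classify_slow_fast(copy.deepcopy(recording))
        assert s1.annotations == s2.annotations

    def test_gap_episode_labeled_missing_and_not_merged(self, tmp_path):
        script = ScanpathScript(
            episodes=(fixation(1000, 0, 0), gap(60), fixation(1000)),
            noise_sd=0.0, seed=52,
        )
        res = generate_recording(script, tmp_path)
        recording, _ = parse_recording(res.recording_dir)
        s = ev.classify_slow_fast(recording)
        labels = [a.label for a in s.annotations]
        assert ev.GAP in labels
        gap_ann = s.annotations[labels.index(ev.GAP)]
        assert gap_ann.duration <= 0.08 + 1e-9  # short but never absorbed


class TestCodingPersistence:
    def _streams(self):
        manual = ev.add_annotation(_stream(), 2.0, "fixation")
        ttl = ev.ttl_stream([TtlEvent(0.5, 1), TtlEvent(1.0, 0)], duration=3.0)
        return [manual, ttl]

    def test_save_load_round_trip(self, tmp_path):
        streams = self._streams()
        ev.save_coding(streams, tmp_path)
        back = ev.load_coding(tmp_path)
        assert len(back) == 2
        for a, b in zip(streams, back):
            assert a.name == b.name
            assert a.annotations == b.annotations
            assert a.locked == b.locked
            assert a.source == b.source

    def test_externally_appended_stream_appears_on_reload(self, tmp_path):
        ev.save_coding(self._streams(), tmp_path)
        # an external manual-mapping tool appends its own stream to the file
        path = tmp_path / ev.CODING_FILE
        payload = json.loads(path.read_text())
        payload["streams"].append(
            {
                "name": "mapping",
                "source": "manual",
                "locked": False,
                "categories": [{"label": "teapot", "flags": []}],
                "annotations": [{"start_s": 0.0, "end_s": 1.0, "label": "teapot", "flags": []}],
            }
        )
        path.write_text(json.dumps(payload))
        back = ev.load_coding(tmp_path)
        assert [s.name for s in back] == ["coding", "ttl", "mapping"]

    def test_empty_directory_yields_no_streams(self, tmp_path):
        assert ev.load_coding(tmp_path) == []

    def test_corrupt_file_is_fatal_with_diagnostics(self, tmp_path):
        (tmp_path / ev.CODING_FILE).write_text("{broken")
        with pytest.raises(ParseError, match="coding"):
            ev.load_coding(tmp_path)
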