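"""Trace/cohort containers, text round trip, window extraction, quality check."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nwrpredict.errors import BoundsError, IntegrityError, ParseError
from nwrpredict.signal_model import (
    Cohort,
    EMGTrace,
    QualityFlag,
    ReflexWindow,
    Subject,
    check_prestim_activity,
    extract_reflex_window,
    load_cohort,
    window_sample_indices,
    write_cohort,
)

from conftest import RATE, TRACE_LEN, balanced_cohort, make_subject, make_trace


class TestInvariants:
    def test_trace_requires_prestim_segment(self):
        with pytest.raises(ValueError, match="pre-stimulation"):
            EMGTrace("S1", 1, 1, np.zeros(400), sampling_rate=2000.0, stim_onset_index=100)

    def test_trace_requires_post_stimulation_coverage(self):
        with pytest.raises(ValueError, match="180 ms"):
            EMGTrace("S1", 1, 1, np.zeros(500), sampling_rate=2000.0, stim_onset_index=400)

    def test_duplicate_site_repetition_rejected(self):
        traces = [make_trace("S1", 1, 1), make_trace("S1", 1, 1)]
        with pytest.raises(IntegrityError, match="duplicate"):
            make_subject("S1", traces=traces)

    def test_duplicate_subject_ids_rejected(self):
        with pytest.raises(IntegrityError, match="duplicate subject ids"):
            Cohort(subjects=[make_subject("S1"), make_subject("S1")])

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            ReflexWindow(0.0, 0.0)
        with pytest.raises(ValueError):
            ReflexWindow(100.0, 60.0)


class TestRoundTrip:
    def test_empty_cohort_round_trips(self, tmp_path):
        write_cohort(Cohort(), tmp_path / "t.tsv", tmp_path / "m.json")
        loaded = load_cohort(tmp_path / "t.tsv", tmp_path / "m.json")
        assert len(loaded) == 0

    def test_metadata_is_lossless(self, tmp_path):
        cohort = Cohort([make_subject("S1", "p", "G2", age=50.0)])
        write_cohort(cohort, tmp_path / "t.tsv", tmp_path / "m.json")
        meta = json.loads((tmp_path / "m.json").read_text())
        assert meta["subjects"][0]["age"] == 50.0
        assert meta["subjects"][0]["group"] == "p"

    def test_single_subject_four_repetitions(self, tmp_path, rng):
        traces = [
            make_trace("S1", 3, r + 1, samples=rng.normal(size=TRACE_LEN))
            for r in range(4)
        ]
        cohort = Cohort([make_subject("S1", traces=traces)])
        write_cohort(cohort, tmp_path / "t.tsv", tmp_path / "m.json")
        loaded = load_cohort(tmp_path / "t.tsv", tmp_path / "m.json")
        assert len(loaded) == 1
        assert len(loaded.subjects[0].traces) == 4
        assert loaded == cohort

    @settings(max_examples=20, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_round_trip_identity_on_random_cohorts(self, tmp_path_factory, seed):
        """load(write(C)) == C with bit-exact amplitudes."""
        rng = np.random.default_rng(seed)
        subjects = []
        for i in range(int(rng.integers(1, 4))):
            traces = [
                make_trace(
                    f"S{i}", int(site), int(rep),
                    samples=rng.normal(scale=rng.uniform(0.1, 100), size=TRACE_LEN),
                )
                for site in rng.choice(np.arange(1, 11), size=2, replace=False)
                for rep in (1, 2)
            ]
            subjects.append(
                make_subject(
                    f"S{i}",
                    group=("h", "p")[int(rng.integers(2))],
                    gender=("G1", "G2")[int(rng.integers(2))],
                    age=float(rng.integers(20, 81)),
                    traces=traces,
                )
            )
        cohort = Cohort(subjects)
        d = tmp_path_factory.mktemp("rt")
        write_cohort(cohort, d / "t.tsv", d / "m.json")
        assert load_cohort(d / "t.tsv", d / "m.json") == cohort


class TestLoadErrors:
    def _meta(self, tmp_path, ids=("S1",)):
        meta = {
            "subjects": [
                {"subject_id": i, "group": "h", "gender": "G1", "age": 30} for i in ids
            ],
            "acquisition": {"sampling_rate_hz": RATE, "prestim_ms": 200.0},
        }
        (tmp_path / "m.json").write_text(json.dumps(meta))
        return tmp_path / "m.json"

    def test_duplicate_rows_rejected(self, tmp_path):
        rows = ["subject_id\tsite_id\trepetition\tsample_index\tamplitude"]
        rows += [f"S1\t1\t1\t{i}\t0.0" for i in range(TRACE_LEN)]
        rows += ["S1\t1\t1\t0\t5.0"]  # same (subject, site, rep, sample)
        (tmp_path / "t.tsv").write_text("\n".join(rows) + "\n")
        with pytest.raises(IntegrityError, match="duplicate"):
            load_cohort(tmp_path / "t.tsv", self._meta(tmp_path))

    def test_malformed_row_names_line(self, tmp_path):
        rows = ["subject_id\tsite_id\trepetition\tsample_index\tamplitude"]
        rows += [f"S1\t1\t1\t{i}\t0.0" for i in range(10)]
        rows[3] = "S1\t1\t1\t2\tnot_a_number"
        (tmp_path / "t.tsv").write_text("\n".join(rows) + "\n")
        with pytest.raises(ParseError, match="line 4"):
            load_cohort(tmp_path / "t.tsv", self._meta(tmp_path))

    def test_trace_subject_missing_from_metadata(self, tmp_path):
        rows = ["subject_id\tsite_id\trepetition\tsample_index\tamplitude"]
        rows += [f"S9\t1\t1\t{i}\t0.0" for i in range(TRACE_LEN)]
        (tmp_path / "t.tsv").write_text("\n".join(rows) + "\n")
        with pytest.raises(IntegrityError, match="S9"):
            load_cohort(tmp_path / "t.tsv", self._meta(tmp_path, ids=("S1",)))


class TestReflexWindow:
    def test_standard_window_has_240_samples_at_2000hz(self):
        trace = EMGTrace("S1", 1, 1, np.zeros(2000), 2000.0, 400)
        assert extract_reflex_window(trace, ReflexWindow(60, 180)).size == 240

    def test_all_zero_trace_gives_zero_window(self):
        trace = make_trace(fill=0.0)
        w = extract_reflex_window(trace, ReflexWindow(60, 180))
        assert w.size == 12 and not w.any()

    def test_window_beyond_trace_is_bounds_error(self):
        with pytest.raises(BoundsError):
            extract_reflex_window(make_trace(), ReflexWindow(60, 300))

    @pytest.mark.parametrize("rate", [100.0, 1000.0, 2000.0, 4096.0])
    @pytest.mark.parametrize("start,end", [(60, 180), (0, 100), (55.5, 179.5)])
    def test_length_formula(self, rate, start, end):
        """Window length = ceil(end*rate/1e3) - ceil(start*rate/1e3), half-open."""
        onset = math.ceil(200 * rate / 1000)
        n = onset + math.ceil(200 * rate / 1000)
        trace = EMGTrace("S1", 1, 1, np.arange(n, dtype=float), rate, onset)
        w = extract_reflex_window(trace, ReflexWindow(start, end))
        expected = math.ceil(end * rate / 1000) - math.ceil(start * rate / 1000)
        assert w.size == expected
        lo, hi = window_sample_indices(ReflexWindow(start, end), rate, onset)
        assert np.array_equal(w, np.arange(lo, hi, dtype=float))


class TestPrestimCheck:
    def test_silent_prestim_passes(self):
        assert check_prestim_activity(make_trace(fill=0.0), 1e-6) is QualityFlag.PASS

    def test_constant_amplitude_fails_half_limit(self):
        c = 3.0
        assert check_prestim_activity(make_trace(fill=c), c / 2) is QualityFlag.FAIL

    def test_sine_rms_is_amplitude_over_sqrt2(self):
        a = 2.0
        t = np.arange(TRACE_LEN)
        # integer number of periods over the 20 prestim samples
        samples = a * np.sin(2 * np.pi * t / 10)
        trace = make_trace(samples=samples)
        limit = a / np.sqrt(2)
        assert check_prestim_activity(trace, limit * 1.001) is QualityFlag.PASS
        assert check_prestim_activity(trace, limit * 0.999) is QualityFlag.FAIL

    @pytest.mark.parametrize("scale", [0.01, 1.0, 1e4])
    def test_scale_equivariance(self, scale, rng):
        samples = rng.normal(size=TRACE_LEN)
        limit = 0.8
        base = check_prestim_activity(make_trace(samples=samples), limit)
        scaled = check_prestim_activity(
            make_trace(samples=samples * scale), limit * scale
        )
        assert base is scaled

    def test_check_does_not_mutate_trace(self):
        samples = np.ones(TRACE_LEN)
        trace = make_trace(samples=samples.copy())
        check_prestim_activity(trace, 10.0)
        assert np.array_equal(trace.samples, samples)
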