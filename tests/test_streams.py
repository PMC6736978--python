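import numpy as np
import pytest

from standshift import (
    AlignmentError,
    DataError,
    EventLog,
    FormatError,
    SessionRecording,
    SpanError,
    TimedStream,
    read_session,
    resample_to_grid,
    synchronize,
    write_session,
)


def make_stream(name, t, values, rate=100.0):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    labels = [f"ch{i}" for i in range(values.shape[1])]
    return TimedStream(name, labels, np.asarray(t, float), values, ["N"] * values.shape[1], rate)


class TestTimedStream:
    def test_invariants_enforced(self):
        with pytest.raises(DataError):
            make_stream("bad", [0.0, 0.0, 1.0], [1.0, 2.0, 3.0])  # non-increasing
        with pytest.raises(DataError):
            TimedStream("bad", ["a"], np.array([0.0, 1.0]), np.zeros((3, 1)), ["N"], 100.0)
        with pytest.raises(DataError):
            TimedStream("bad", ["a", "b"], np.array([0.0, 1.0]), np.zeros((2, 1)), ["N"], 100.0)

    def test_channel_selection(self):
        s = TimedStream(
            "plate", ["Fx", "Fz"], np.array([0.0, 1.0]), np.array([[1.0, 2.0], [3.0, 4.0]]),
            ["N", "N"], 100.0,
        )
        assert np.allclose(s.channel("Fz"), [2.0, 4.0])
        sel = s.select("Fz")
        assert sel.channel_labels == ["Fz"] and sel.values.shape == (2, 1)
        with pytest.raises(DataError):
            s.channel("Mz")


class TestResample:
    def test_constant_stays_constant(self):
        s = make_stream("c", [0.0, 0.7, 1.3, 2.0], [5.0, 5.0, 5.0, 5.0])
        out = resample_to_grid(s, 10.0, 0.0, 2.0)
        assert np.allclose(out.values, 5.0)

    def test_linear_ramp_interpolates(self):
        s = make_stream("r", [0.0, 1.0], [0.0, 1.0])
        out = resample_to_grid(s, 4.0, 0.0, 1.0)
        assert np.allclose(out.values[:, 0], [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_sample_count_floor_rule(self):
        # irregular stream spanning 3.0 s at 100 Hz -> floor(3*100)+1 = 301 samples
        t = np.sort(np.random.default_rng(0).uniform(0, 3.0, 50))
        t[0], t[-1] = 0.0, 3.0
        out = resample_to_grid(make_stream("i", t, np.sin(t)), 100.0, 0.0, 3.0)
        assert out.n_samples == 301
        assert np.allclose(np.diff(out.timestamps), 0.01)

    def test_span_violation_and_short_input(self):
        s = make_stream("r", [0.0, 1.0], [0.0, 1.0])
        with pytest.raises(SpanError):
            resample_to_grid(s, 10.0, -0.5, 1.0)
        with pytest.raises(DataError):
            resample_to_grid(make_stream("one", [0.0], [1.0]), 10.0, 0.0, 0.0)

    def test_idempotent_on_uniform_stream(self):
        t = np.arange(0, 2.0, 0.01)
        s = make_stream("u", t, np.sin(t))
        out = resample_to_grid(s, 100.0, 0.0, t[-1])
        assert np.allclose(out.values, s.values, atol=1e-12)


class TestSynchronize:
    def test_identity_on_shared_grid(self):
        t = np.arange(0, 1.0, 0.01)
        a = make_stream("a", t, np.cos(t))
        b = make_stream("b", t, np.sin(t))
        out = synchronize([a, b], 100.0)
        assert np.allclose(out["a"].values, a.values, atol=1e-12)

    def test_overlap_intersection(self):
        a = make_stream("a", np.linspace(0, 10, 101), np.zeros(101))
        b = make_stream("b", np.linspace(2, 12, 101), np.ones(101))
        out = synchronize([a, b], 10.0)
        for s in out.values():
            assert s.span == (2.0, 10.0)

    def test_disjoint_spans_raise(self):
        a = make_stream("a", [0.0, 1.0], [0.0, 1.0])
        b = make_stream("b", [2.0, 3.0], [0.0, 1.0])
        with pytest.raises(AlignmentError):
            synchronize([a, b], 10.0)

    def test_never_extends_any_span(self, rng):
        starts = rng.uniform(0, 1, 3)
        a, b, c = (
            make_stream(n, np.linspace(s, s + 5, 60), rng.normal(size=60))
            for n, s in zip("abc", starts)
        )
        out = synchronize([a, b, c], 20.0)
        lo, hi = out["a"].span
        assert lo >= starts.max() - 1e-9 and hi <= starts.min() + 5 + 1e-9


def random_recording(rng, n=50, rate=50.0):
    t = np.arange(n) / rate
    streams = {}
    for name, labels, units in [
        ("plate_left", ["Fx", "Fy", "Fz", "Mx", "My", "Mz"], ["N"] * 3 + ["N*m"] * 3),
        ("markers", ["clavicle_x", "clavicle_y", "clavicle_z"], ["m"] * 3),
    ]:
        streams[name] = TimedStream(
            name, labels, t, rng.normal(scale=100, size=(n, len(labels))), units, rate
        )
    return SessionRecording(
        participant_id="PX",
        session_index=3,
        body_mass=72.7,
        wheelchair_mass=16.7,
        streams=streams,
        events=EventLog([(0.0, "stand_start"), (0.2, "exercise_start")]),
        grid_rate=rate,
    )


class TestContainerRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_lossless_to_stated_precision(self, tmp_path, seed):
        rec = random_recording(np.random.default_rng(seed))
        write_session(rec, tmp_path / "sess")
        back = read_session(tmp_path / "sess")
        assert back.participant_id == rec.participant_id
        assert back.session_index == rec.session_index
        assert back.body_mass == rec.body_mass
        assert back.events.entries == rec.events.entries
        for name in rec.streams:
            np.testing.assert_allclose(
                back.streams[name].values, rec.streams[name].values, atol=5e-7
            )
            assert back.streams[name].units == rec.streams[name].units

    def test_empty_event_log_preserved(self, tmp_path, rng):
        rec = random_recording(rng)
        rec.events = EventLog([])
        write_session(rec, tmp_path / "s")
        assert read_session(tmp_path / "s").events.entries == []

    def test_missing_sidecar_is_format_error(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(FormatError, match="session.json"):
            read_session(tmp_path / "empty")

    def test_missing_stream_file_named_in_error(self, tmp_path, rng):
        rec = random_recording(rng)
        write_session(rec, tmp_path / "s")
        (tmp_path / "s" / "markers.csv").unlink()
        with pytest.raises(FormatError, match="markers"):
            read_session(tmp_path / "s")


class TestEventLog:
    def test_vocabulary_and_order_enforced(self):
        with pytest.raises(DataError):
            EventLog([(0.0, "coffee_break")])
        with pytest.raises(DataError):
            EventLog([(5.0, "stand_start"), (1.0, "sit_start")])

    def test_exclusion_intervals(self):
        log = EventLog(
            [
                (0.0, "stand_start"),
                (10.0, "exercise_start"),
                (100.0, "rest_start"),
                (130.0, "rest_end"),
                (600.0, "sit_start"),
            ]
        )
        ivals = log.exclusion_intervals(650.0)
        assert (100.0, 130.0) in ivals
        assert any(b == 10.0 for _, b in ivals)  # pre-exercise interval
        assert any(a == 600.0 for a, _ in ivals)  # post sit-down
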