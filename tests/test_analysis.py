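import numpy as np
import pytest

from standshift import (
    DataError,
    GeometryError,
    SpanError,
    TimedStream,
    analyze_session,
    detect_cycle_peaks,
    lean_angle,
    range_of_motion,
    sample_at_peaks,
    summarize_session,
    to_bw_percent,
)
from standshift.analysis import ExerciseCycle
from standshift.sensing import GRAVITY


def fz_stream(values, rate=100.0):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) / rate
    return TimedStream("fz", ["Fz"], t, values[:, None], ["N"], rate)


def bump_trace(peaks, duration, rate=100.0, width=1.0):
    """Smooth trace with Gaussian bumps at (time, height) pairs."""
    t = np.arange(int(duration * rate)) / rate
    x = np.zeros_like(t)
    for tc, h in peaks:
        x += h * np.exp(-0.5 * ((t - tc) / width) ** 2)
    return fz_stream(x, rate)


class TestBwPercent:
    def test_body_weight_is_100_percent(self):
        assert to_bw_percent(72.7 * GRAVITY, 72.7) == pytest.approx(100.0)

    def test_zero_and_sign_preserved(self):
        assert to_bw_percent(0.0, 60.0) == 0.0
        assert to_bw_percent(-50.0, 60.0) < 0  # pull forces stay negative

    def test_reference_conversion(self):
        assert to_bw_percent(400.0, 83.3) == pytest.approx(48.95, abs=0.01)

    def test_non_positive_mass_rejected(self):
        with pytest.raises(DataError):
            to_bw_percent(100.0, 0.0)


def brute_force_peaks(t, x, threshold, min_sep):
    """Independent oracle: all strict local maxima over threshold, then
    iteratively drop the smaller of any pair closer than min_sep."""
    cand = [
        i
        for i in range(1, len(x) - 1)
        if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] >= threshold
    ]
    cand = [i for i in cand if t[i] - t[0] >= min_sep and t[-1] - t[i] >= min_sep]
    changed = True
    while changed:
        changed = False
        for a in range(len(cand)):
            for b in range(a + 1, len(cand)):
                if abs(t[cand[b]] - t[cand[a]]) < min_sep:
                    drop = a if x[cand[a]] <= x[cand[b]] else b
                    cand.pop(drop)
                    changed = True
                    break
            if changed:
                break
    return np.array([t[i] for i in cand]), np.array([x[i] for i in cand])


class TestDetectCyclePeaks:
    BODY = 70.0
    MG = 70.0 * GRAVITY

    def test_constant_below_threshold_yields_nothing(self):
        s = fz_stream(np.full(3000, 0.4 * self.MG))
        times, _ = detect_cycle_peaks(s, self.BODY)
        assert times.size == 0

    def test_two_separated_bumps_both_found(self):
        s = bump_trace([(12.0, 0.6 * self.MG), (18.0, 0.6 * self.MG)], 30.0)
        times, values = detect_cycle_peaks(s, self.BODY)
        assert times.size == 2
        np.testing.assert_allclose(times, [12.0, 18.0], atol=0.02)
        assert np.all(values >= 0.5 * self.MG)

    def test_close_bumps_keep_the_larger(self):
        s = bump_trace([(12.0, 0.6 * self.MG), (15.0, 0.7 * self.MG)], 30.0)
        times, values = detect_cycle_peaks(s, self.BODY)
        assert times.size == 1
        assert values[0] == pytest.approx(np.max(s.values), abs=1.0)

    def test_plateau_reports_first_sample(self):
        x = np.zeros(3000)
        x[1000:1010] = 0.8 * self.MG  # flat maximum
        times, _ = detect_cycle_peaks(fz_stream(x), self.BODY)
        assert times.size == 1
        assert times[0] == pytest.approx(10.0)

    def test_edge_truncated_peaks_dropped(self):
        s = bump_trace([(2.0, 0.8 * self.MG), (15.0, 0.8 * self.MG)], 18.0)
        times, _ = detect_cycle_peaks(s, self.BODY)
        # both peaks sit within min_sep of a recording edge
        assert times.size == 0

    def test_excluded_interval_drops_peaks(self):
        s = bump_trace([(12.0, 0.8 * self.MG), (22.0, 0.8 * self.MG)], 34.0)
        times, _ = detect_cycle_peaks(s, self.BODY, exclude=[(20.0, 25.0)])
        np.testing.assert_allclose(times, [12.0], atol=0.02)

    def test_empty_stream_rejected(self):
        empty = TimedStream("fz", ["Fz"], np.empty(0), np.empty((0, 1)), ["N"], 100.0)
        with pytest.raises(DataError):
            detect_cycle_peaks(empty, self.BODY)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle_on_random_traces(self, seed):
        r = np.random.default_rng(seed)
        n_bumps = r.integers(3, 10)
        centers = np.sort(r.uniform(6, 54, n_bumps))
        heights = r.uniform(0.3, 0.9, n_bumps) * self.MG
        s = bump_trace(list(zip(centers, heights)), 60.0, width=r.uniform(0.5, 1.5))
        got_t, got_v = detect_cycle_peaks(s, self.BODY)
        exp_t, exp_v = brute_force_peaks(
            s.timestamps, s.values[:, 0], 0.5 * self.MG, 5.0
        )
        np.testing.assert_allclose(got_t, exp_t)
        np.testing.assert_allclose(got_v, exp_v)
        # output invariants: spacing and threshold
        assert np.all(np.diff(got_t) >= 5.0)
        assert np.all(got_v >= 0.5 * self.MG)


class TestSampleAtPeaks:
    def test_on_and_off_grid(self, short_quiet_session):
        _, _, rec = short_quiet_session
        t = rec.time
        vals = sample_at_peaks(rec, [t[500], t[500] + 0.005])
        fz = rec.streams["plate_left"].channel("Fz")
        assert vals["plate_left"][0, 2] == pytest.approx(fz[500])
        assert vals["plate_left"][1, 2] == pytest.approx((fz[500] + fz[501]) / 2, abs=1e-9)

    def test_outside_span_rejected(self, short_quiet_session):
        _, _, rec = short_quiet_session
        with pytest.raises(SpanError):
            sample_at_peaks(rec, [rec.span[1] + 1.0])


class TestLeanAngle:
    def test_centered_and_diagonal(self):
        assert lean_angle([0.0, 0.0, 1.35], [0.0, 0.0, 1.35]) == pytest.approx(0.0)
        assert lean_angle([1.0, 0.0, 1.0], [0.0, 0.0, 1.0]) == pytest.approx(45.0)

    def test_small_angle(self):
        assert lean_angle([0.135, 0.0, 1.35], [0.0, 0.0, 1.35]) == pytest.approx(5.71, abs=0.01)

    def test_zero_height_rejected(self):
        with pytest.raises(GeometryError):
            lean_angle([0.1, 0.0, 0.0], [0.0, 0.0, 0.0])


def cycle(side, t, angle):
    return ExerciseCycle(side, t, 600.0, 75.0, {}, {}, angle)


class TestRangeOfMotion:
    def test_pair_sum_of_absolutes(self):
        roms = range_of_motion([cycle("L", 10, -6.0), cycle("R", 15, 6.0)])
        assert roms == [pytest.approx(12.0)]

    def test_early_session_scale(self):
        roms = range_of_motion([cycle("L", 10, -6.0), cycle("R", 15, 6.13)])
        assert roms == [pytest.approx(12.13)]

    def test_single_cycle_is_unpaired(self):
        assert range_of_motion([cycle("L", 10, -6.0)]) == []

    def test_trailing_unpaired_dropped(self):
        roms = range_of_motion(
            [cycle("L", 10, -5.0), cycle("R", 15, 5.0), cycle("L", 20, -7.0)]
        )
        assert len(roms) == 1

    def test_invariant_to_common_lateral_offset(self):
        clav = np.array([[0.1, 0.0, 1.3], [-0.12, 0.0, 1.31]])
        ref = np.array([0.01, 0.0, 1.3])
        base = [lean_angle(c, ref) for c in clav]
        shifted = [lean_angle(c + [0.05, 0, 0], ref + [0.05, 0, 0]) for c in clav]
        assert abs(base[0]) + abs(base[1]) == pytest.approx(
            abs(shifted[0]) + abs(shifted[1]), abs=1e-9
        )


class TestSummarize:
    def test_no_cycles_flagged_undefined(self, short_quiet_session):
        _, _, rec = short_quiet_session
        summary = summarize_session(rec, [])
        assert summary.cycle_count == 0
        assert not summary.defined
        assert summary.support_mean_bw is None

    def test_identical_peaks_have_zero_sd(self, short_quiet_session):
        _, _, rec = short_quiet_session
        cycles = [
            ExerciseCycle("L", 20.0, 600.0, 75.0,
                          {k: 10.0 for k in ("left_leg", "right_leg", "left_arm", "right_arm")},
                          {k: 5.0 for k in ("left_leg", "right_leg", "left_arm", "right_arm")},
                          -6.0),
        ] * 4
        summary = summarize_session(rec, cycles)
        assert summary.support_sd_bw == 0.0

    def test_count_matches_pipeline(self, short_quiet_session):
        _, _, rec = short_quiet_session
        cycles, summary = analyze_session(rec)
        assert summary.cycle_count == len(cycles)
        assert len(summary.profile_bw) == len(cycles)
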