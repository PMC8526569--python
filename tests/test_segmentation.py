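import numpy as np
import pytest

from steerstress.canbus_io import SpeedTrace, SteeringTrace
from steerstress.errors import InsufficientDataError
from steerstress.segmentation import (
    SegmentationParams,
    driving_behaviour_metrics,
    extract_segments,
    monotone_runs,
    restrict_to_initial_window,
    to_absolute,
)

from conftest import ramp_trace


def brute_force_segments(x, lower, upper):
    """Reference scan: explicit per-index walk, independent of the library path.

    Returns (valley_value, untruncated_peak_value, retained_last_value) per
    retained segment.
    """
    out = []
    n = len(x)
    i = 0
    while i < n - 1:
        if x[i + 1] < x[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and x[j + 1] >= x[j]:
            j += 1
        # strip a trailing plateau down to its first sample
        p = j
        while p > i and x[p] == x[p - 1]:
            p -= 1
        if x[p] - x[i] >= lower:
            last = x[p]
            for idx in range(i, p + 1):
                if x[idx] - x[i] > upper:
                    last = x[idx - 1]
                    break
            out.append((x[i], x[p], last))
        i = j
    return out


class TestToAbsolute:
    def test_signed_examples(self):
        tr = SteeringTrace(time=[0, 0.01, 0.02], angle=[-30.0, 0.0, 45.0])
        np.testing.assert_allclose(to_absolute(tr).angle, [30.0, 0.0, 45.0])

    def test_nonnegative_unchanged(self):
        tr = SteeringTrace(time=[0, 0.01], angle=[10.0, 20.0])
        np.testing.assert_array_equal(to_absolute(tr).angle, tr.angle)

    def test_property_nonnegative(self, rng):
        tr = SteeringTrace(time=np.arange(100) * 0.01, angle=rng.uniform(-450, 450, 100))
        out = to_absolute(tr).angle
        assert np.all(out >= 0)
        np.testing.assert_array_equal(np.abs(out), out)


class TestExtractSegments:
    def test_triangular_excursion(self, default_params):
        tr = ramp_trace([0, 60, 0])
        segs = extract_segments(tr, default_params)
        assert len(segs) == 1
        s = segs[0]
        assert s.amplitude == pytest.approx(60.0)
        assert not s.truncated
        assert np.all(np.diff(s.samples) >= 0)

    def test_small_excursion_filtered(self, default_params):
        assert extract_segments(ramp_trace([0, 30, 0]), default_params) == []

    def test_truncation_at_upper_bound(self, default_params):
        tr = ramp_trace([0, 200, 0])
        (s,) = extract_segments(tr, default_params)
        assert s.truncated
        assert s.samples[-1] - s.valley_angle <= 150.0
        # oracle: first 150-crossing of the constructed 200 deg/s ramp
        ramp = tr.angle[:201]
        first_over = np.flatnonzero(ramp > 150.0)[0]
        assert s.samples.size == first_over
        assert s.amplitude == pytest.approx(200.0)  # untruncated amplitude kept

    def test_too_short_trace(self, default_params):
        with pytest.raises(InsufficientDataError):
            extract_segments(SteeringTrace(time=[0, 0.01], angle=[0, 1]), default_params)

    def test_plateau_peak_cut_at_first_sample(self):
        angle = np.concatenate([np.linspace(0, 50, 51), [50, 50], np.linspace(49, 0, 50)])
        tr = SteeringTrace(time=np.arange(angle.size) * 0.01, angle=angle)
        (s,) = extract_segments(tr, SegmentationParams(lower_bound=40))
        assert s.samples[-1] == 50.0
        assert s.samples.size == 51  # trailing plateau excluded

    def test_boundary_extrema_included(self, default_params):
        # drive begins mid-rise and ends mid-rise: both boundary runs count
        angle = np.concatenate([np.linspace(10, 70, 100), np.linspace(69, 5, 80),
                                np.linspace(6, 60, 90)])
        tr = SteeringTrace(time=np.arange(angle.size) * 0.01, angle=angle)
        segs = extract_segments(tr, default_params)
        assert len(segs) == 2
        assert segs[0].valley_angle == pytest.approx(10.0)
        assert segs[1].peak_angle == pytest.approx(60.0)

    def test_matches_brute_force_on_random_waypoints(self, rng, default_params):
        for _ in range(20):
            pts = rng.uniform(0, 250, rng.integers(4, 10)).round(1)
            tr = ramp_trace(list(pts))
            segs = extract_segments(tr, default_params)
            oracle = brute_force_segments(tr.angle, 40.0, 150.0)
            assert len(segs) == len(oracle)
            for s, (v, p, last) in zip(segs, oracle):
                assert s.valley_angle == pytest.approx(v)
                assert s.peak_angle == pytest.approx(p)
                assert s.samples[-1] == pytest.approx(last)


class TestSegmentProperties:
    def test_samples_above_valley_and_monotone(self, rng, default_params):
        pts = rng.uniform(0, 300, 12)
        segs = extract_segments(ramp_trace(list(pts)), default_params)
        for s in segs:
            assert np.all(s.samples >= s.valley_angle)
            assert np.all(np.diff(s.samples) >= 0)

    def test_lower_bound_monotonicity(self, rng):
        pts = rng.uniform(0, 300, 12)
        tr = ramp_trace(list(pts))
        counts = [
            len(extract_segments(tr, SegmentationParams(lower_bound=lb)))
            for lb in (20, 40, 60, 80, 100)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_upper_bound_monotone_retained_length(self, rng):
        pts = rng.uniform(0, 300, 12)
        tr = ramp_trace(list(pts))
        prev_lengths = None
        for ub in (60, 100, 150, 250, 400):
            segs = extract_segments(tr, SegmentationParams(upper_bound=ub))
            lengths = [len(s) for s in segs]
            if prev_lengths is not None:
                assert len(lengths) == len(prev_lengths)
                assert all(b >= a for a, b in zip(prev_lengths, lengths))
            prev_lengths = lengths

    def test_resegmentation_stability(self, rng, default_params):
        pts = rng.uniform(0, 300, 10)
        tr = ramp_trace(list(pts))
        for s in extract_segments(tr, SegmentationParams(lower_bound=40, upper_bound=np.inf)):
            sub = SteeringTrace(time=s.times, angle=s.samples)
            resegs = extract_segments(sub, SegmentationParams(lower_bound=40, upper_bound=np.inf))
            assert len(resegs) == 1
            np.testing.assert_array_equal(resegs[0].samples, s.samples)


def test_monotone_runs_simple():
    x = np.array([3.0, 1.0, 2.0, 2.0, 5.0, 4.0, 6.0])
    assert monotone_runs(x) == [(1, 4), (5, 6)]


class TestInitialWindow:
    def test_threshold_comparison(self, default_params):
        segs = [
            _seg(start) for start in (5.0, 100.0, 120.0)
        ]
        kept = restrict_to_initial_window(segs, default_params)
        assert [s.start_time for s in kept] == [5.0, 100.0]

    def test_empty(self, default_params):
        assert restrict_to_initial_window([], default_params) == []

    def test_count_oracle(self, rng, default_params):
        starts = rng.uniform(0, 300, 40)
        segs = [_seg(t) for t in np.sort(starts)]
        kept = restrict_to_initial_window(segs, default_params)
        assert len(kept) == int(np.sum(starts < 110.0))


def _seg(start):
    from steerstress.segmentation import TurnSegment

    return TurnSegment(
        participant_id="P", condition=None, start_time=start, end_time=start + 2.0,
        times=np.array([start, start + 2.0]), samples=np.array([0.0, 50.0]),
        valley_angle=0.0, peak_angle=50.0, amplitude=50.0, truncated=False,
    )


class TestDrivingBehaviourMetrics:
    def test_constant_speed_and_duration(self):
        segs = [_seg(1.0)]
        sp = SpeedTrace(time=np.arange(0, 10, 0.02), speed=np.full(500, 10.0))
        df = driving_behaviour_metrics(segs, sp)
        assert df.loc[0, "mean_speed"] == pytest.approx(10.0)
        assert df.loc[0, "duration"] == pytest.approx(2.0)

    def test_filtered_mean_oracle(self, rng):
        seg = _seg(2.0)
        t = np.arange(0, 10, 0.02)
        v = rng.uniform(5, 25, t.size)
        df = driving_behaviour_metrics([seg], SpeedTrace(time=t, speed=v))
        mask = (t >= seg.start_time) & (t <= seg.end_time)
        assert df.loc[0, "mean_speed"] == pytest.approx(v[mask].mean())

    def test_missing_speed_flagged(self):
        seg = _seg(100.0)
        sp = SpeedTrace(time=[0.0, 1.0], speed=[10.0, 10.0])
        df = driving_behaviour_metrics([seg], sp)
        assert bool(df.loc[0, "speed_missing"])
        assert np.isnan(df.loc[0, "mean_speed"])
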