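"""Widefield event detection, control frames and temporal autocorrelation."""

import numpy as np
import pytest

from modcortex.events import (
    _split_runs_at_minima,
    detect_events,
    find_active_pixels,
    select_control_frames,
    temporal_autocorrelation,
)
from modcortex.preprocess import DffMovie


def _dff(data, pixel_um=19.0, rate=15.0):
    data = np.asarray(data, dtype=float)
    return DffMovie(
        data=data,
        baseline=np.ones(data.shape[1:]),
        pixel_um=pixel_um,
        frame_rate_hz=rate,
        roi_mask=np.ones(data.shape[1:], dtype=bool),
    )


class TestActivePixels:
    def setup_method(self):
        self.shape = (30, 30)
        self.mean = np.zeros(self.shape)
        self.sd = np.ones(self.shape)
        self.mask = np.ones(self.shape, bool)

    def test_frame_at_mean_inactive(self):
        act = find_active_pixels(np.zeros(self.shape), self.mean, self.sd, 19.0, self.mask)
        assert not act.any()

    def test_patch_above_area_threshold_active(self):
        # 0.12 mm square at 19 um pitch: 7x7 pixels, 0.0144 mm^2 >= 0.01
        frame = np.zeros(self.shape)
        frame[10:17, 10:17] = 5.0
        act = find_active_pixels(frame, self.mean, self.sd, 19.0, self.mask)
        assert act[10:17, 10:17].all()
        assert act.sum() == 49

    def test_isolated_pixel_inactive(self):
        # one 19 um pixel is 3.6e-4 mm^2, below the 0.01 mm^2 minimum
        frame = np.zeros(self.shape)
        frame[5, 5] = 10.0
        act = find_active_pixels(frame, self.mean, self.sd, 19.0, self.mask)
        assert not act.any()

    def test_zero_sd_pixels_never_active(self):
        sd = self.sd.copy()
        sd[3, 3] = 0.0
        frame = np.full(self.shape, 10.0)
        with pytest.warns(UserWarning, match="zero-SD"):
            act = find_active_pixels(frame, self.mean, sd, 19.0, self.mask)
        assert not act[3, 3]


class TestDetectEvents:
    def test_run_with_interior_minimum_splits_in_two(self):
        # ROI-mean values 1,3,2,1.5,4,2 within one run: the 1.5 frame is a
        # strict interior minimum and ends the earlier event
        run = np.arange(6)
        trace = np.array([1.0, 3.0, 2.0, 1.5, 4.0, 2.0])
        pieces = _split_runs_at_minima(run, trace)
        assert [p.tolist() for p in pieces] == [[0, 1, 2, 3], [4, 5]]

    def test_quiescent_movie_yields_no_events(self):
        rng = np.random.default_rng(0)
        dff = _dff(rng.normal(0, 0.01, (200, 20, 20)))
        assert len(detect_events(dff)) == 0

    def test_planted_events_recovered(self, wf_movie20):
        ev = wf_movie20["events"]
        truth = wf_movie20["truth"]
        assert len(ev) == 20
        assert np.abs(ev.event_frames - truth.event_times).max() <= 1

    def test_event_frame_is_span_maximum(self, wf_movie20):
        dff = wf_movie20["dff"]
        trace = dff.roi_mean_trace()
        for e in wf_movie20["events"].events:
            span = trace[e.start_frame : e.end_frame + 1]
            assert trace[e.event_frame] == pytest.approx(span.max())

    def test_count_monotone_in_active_fraction(self, wf_movie20):
        dff = wf_movie20["dff"]
        counts = [len(detect_events(dff, active_fraction=af)) for af in (0.4, 0.6, 0.8)]
        assert counts[0] >= counts[1] >= counts[2]


class TestControlFrames:
    def test_counting_and_pool_decile(self):
        rng = np.random.default_rng(1)
        data = rng.random((1000, 5, 5))
        dff = _dff(data)
        ev = detect_events(dff)  # no events in uniform noise
        assert len(ev) == 0
        # emulate 12 events by injecting spans
        from modcortex.events import Event, EventSet

        events = [
            Event(i * 50, i * 50 + 2, i * 50 + 1, data[i * 50 + 1], 0.0)
            for i in range(12)
        ]
        evset = EventSet(events, (5, 5), 19.0, 15.0, dff.roi_mask)
        ctrl = select_control_frames(dff, evset, n_sets=100, seed=3)
        non_event = 1000 - 12 * 3
        assert ctrl.pool.size == int(np.ceil(non_event * 0.10))
        assert all(s.size == 12 for s in ctrl.sets)
        assert len(ctrl.sets) == 100
        covered = evset.frame_in_event(1000)
        assert not covered[ctrl.pool].any()

    def test_same_seed_identical_sets(self, wf_movie20):
        dff, ev = wf_movie20["dff"], wf_movie20["events"]
        a = select_control_frames(dff, ev, n_sets=5, seed=9)
        b = select_control_frames(dff, ev, n_sets=5, seed=9)
        for x, y in zip(a.sets, b.sets):
            assert np.array_equal(x, y)

    def test_zero_events_empty_sets(self):
        dff = _dff(np.random.default_rng(2).random((100, 4, 4)))
        from modcortex.events import EventSet

        evset = EventSet([], (4, 4), 19.0, 15.0, dff.roi_mask)
        ctrl = select_control_frames(dff, evset, n_sets=10, seed=0)
        assert all(s.size == 0 for s in ctrl.sets)


class TestTemporalAutocorrelation:
    def test_lag_zero_is_unity(self):
        dff = _dff(np.random.default_rng(3).random((400, 3, 3)))
        _, r = temporal_autocorrelation(dff, max_lag_s=2.0)
        assert r[0] == 1.0

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(4)
        trace = rng.normal(size=10_000)
        dff = _dff(trace[:, None, None] * np.ones((1, 2, 2)))
        _, r = temporal_autocorrelation(dff, max_lag_s=1.0)
        assert np.abs(r[1:]).max() < 0.05

    def test_sine_wave_periodicity(self):
        t = np.arange(3000)
        period = 150
        trace = np.sin(2 * np.pi * t / period)
        dff = _dff(trace[:, None, None] * np.ones((1, 2, 2)))
        lags, r = temporal_autocorrelation(dff, max_lag_s=period / 15.0)
        assert r[period] == pytest.approx(1.0, abs=1e-3)

    def test_constant_trace_raises(self):
        dff = _dff(np.ones((300, 2, 2)))
        with pytest.raises(ValueError, match="constant"):
            temporal_autocorrelation(dff, max_lag_s=1.0)
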