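"""Missing-value handling, displacement integration, event filters, registration."""

import numpy as np
import pytest

from edgeclust import registration as reg
from edgeclust import synthetic as syn


class TestImputeMissing:
    def test_long_missing_run_rejects_series(self):
        x = np.arange(30.0)
        x[5:14] = np.nan  # run of 9 > 8
        assert reg.impute_missing(x) is None

    def test_no_missing_returns_unchanged(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(reg.impute_missing(x), x)

    def test_flanking_mean_imputation(self):
        x = np.array([1, 2, 3, 4, np.nan, 6, 7, 8, 9], dtype=float)
        assert reg.impute_missing(x)[4] == pytest.approx(5.0)

    def test_all_missing_rejected(self):
        assert reg.impute_missing(np.full(10, np.nan)) is None

    def test_run_of_eight_is_imputed(self):
        x = np.arange(40.0)
        x[10:18] = np.nan  # run of exactly 8 is tolerated
        out = reg.impute_missing(x)
        assert out is not None and np.all(np.isfinite(out))


class TestDisplacement:
    def test_constant_velocity_integrates_linearly(self):
        d = reg.velocity_to_displacement(np.full(11, 10.0), dt=5.0)
        assert d[0] == 0.0
        assert d[10] == pytest.approx(500.0)

    def test_zero_velocity_zero_displacement(self):
        np.testing.assert_array_equal(reg.velocity_to_displacement(np.zeros(20), 5.0), np.zeros(20))

    def test_ramp_matches_trapezoid_by_hand(self):
        d = reg.velocity_to_displacement(np.arange(5.0), dt=1.0)
        np.testing.assert_allclose(d, [0.0, 0.5, 2.0, 4.5, 8.0])

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            reg.velocity_to_displacement(np.array([1.0, np.nan, 2.0]))


class TestSmoothing:
    def test_param_one_interpolates(self, rng):
        x = rng.normal(size=30)
        np.testing.assert_allclose(reg.smooth_displacement(x, 1.0), x, atol=1e-9)

    def test_param_to_zero_approaches_least_squares_line(self, rng):
        t = np.arange(50.0) * 5.0
        y = 3.0 * t + 10 + rng.normal(0, 5, 50)
        line = np.polyval(np.polyfit(t, y, 1), t)
        out = reg.smooth_displacement(y, 1e-9)
        np.testing.assert_allclose(out, line, atol=0.5)

    def test_denoising_reduces_residual_variance(self, rng):
        t = np.arange(100.0)
        clean = 100 * np.sin(2 * np.pi * t / 50)
        noisy = clean + rng.normal(0, 10, 100)
        out = reg.smooth_displacement(noisy, 0.01, dt=5.0)
        assert np.var(out - clean) < np.var(noisy - clean)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            reg.smooth_displacement(np.array([1.0, 2.0, 3.0]))


class TestDetectEvents:
    dt = 5.0

    def _trace(self, events, n_frames):
        m = syn.generate_raw_window_map(1, n_frames, events, seed=0)
        d = reg.velocity_to_displacement(m.values[0], self.dt)
        return reg.smooth_displacement(d, 0.01, self.dt)

    def test_single_large_protrusion_yields_one_event(self):
        s = self._trace([dict(window=0, onset=20, end=80, distance_nm=1500)], 100)
        events = reg.detect_events(s, self.dt)
        assert len(events) == 1
        assert abs(events[0].onset_frame - 20) <= 2
        assert events[0].net_distance_nm >= 720

    def test_small_protrusion_filtered_by_distance_rule(self):
        s = self._trace([dict(window=0, onset=20, end=80, distance_nm=500)], 100)
        assert reg.detect_events(s, self.dt) == []

    def test_one_of_two_protrusions_survives(self):
        s = self._trace(
            [
                dict(window=0, onset=20, end=80, distance_nm=1500),
                dict(window=0, onset=120, end=170, distance_nm=500),
            ],
            200,
        )
        assert len(reg.detect_events(s, self.dt)) == 1

    def test_short_dip_merged_into_long_protrusion(self):
        t = np.arange(120.0)
        # 8-frame (40 s) dip at frames 50-58 inside a 90-frame protrusion
        disp = np.interp(t, [0, 10, 50, 58, 100, 120], [0, -50, 1400, 1300, 2500, 2400])
        events = reg.detect_events(disp, self.dt)
        assert len(events) == 1
        assert events[0].onset_frame == 10

    def test_monotone_trace_yields_no_retraction_events(self):
        assert reg.detect_events(-10.0 * np.arange(100.0), self.dt) == []

    def test_filtering_idempotent_on_clean_trace(self):
        s = self._trace([dict(window=0, onset=20, end=80, distance_nm=1500)], 100)
        ev1 = reg.detect_events(s, self.dt)
        seg = s[ev1[0].onset_frame : ev1[0].end_frame + 1]
        ev2 = reg.detect_events(seg, self.dt)
        assert len(ev2) == 1
        assert ev2[0].net_distance_nm == pytest.approx(ev1[0].net_distance_nm, rel=1e-9)


class TestRegisterAndSelect:
    def _map(self, n_frames=120):
        values = np.tile(np.sin(np.arange(n_frames) / 5.0), (2, 1))
        return reg.WindowTimeSeriesMap(values=values)

    def test_onset_maps_to_pre_frames_column(self):
        m = self._map()
        ev = reg.ProtrusionEvent(window_id=0, onset_frame=20, end_frame=90, net_distance_nm=1000)
        out = reg.register(m, [ev])
        assert out[0].pre_len == 5
        assert out[0].values[5] == m.values[0, 20]

    def test_two_events_keep_provenance(self):
        m = self._map()
        evs = [
            reg.ProtrusionEvent(0, 20, 60, 1000.0),
            reg.ProtrusionEvent(0, 70, 110, 1000.0),
        ]
        out = reg.register(m, evs, movie_id="m1")
        assert [(s.movie_id, s.window_id, s.onset_frame) for s in out] == [("m1", 0, 20), ("m1", 0, 70)]

    def test_early_onset_truncates_pre_segment_and_flags(self):
        m = self._map()
        ev = reg.ProtrusionEvent(0, 3, 80, 1000.0)
        out = reg.register(m, [ev])
        assert out[0].pre_len == 3 and out[0].pre_truncated

    def test_event_outside_map_rejected(self):
        m = self._map(50)
        with pytest.raises(ValueError):
            reg.register(m, [reg.ProtrusionEvent(0, 20, 60, 1000.0)])

    def test_length_selection_maximizes_samples_times_length(self):
        series = []
        for i, post in enumerate([60] * 10 + [30] * 5):
            series.append(
                reg.RegisteredSeries(values=np.zeros(5 + post), pre_len=5, movie_id="m", window_id=i, onset_frame=10)
            )
        # brute-force oracle over all candidate lengths
        posts = np.array([s.post_len for s in series])
        expected = max(np.unique(posts), key=lambda L: (posts >= L).sum() * L)
        assert expected == 60
        out = reg.select_time_length(series)
        assert out.n_frames == 5 + 60 and out.n_samples == 10

    def test_uniform_lengths_all_retained(self):
        series = [
            reg.RegisteredSeries(np.zeros(56), 5, "m", i, 10) for i in range(8)
        ]
        out = reg.select_time_length(series)
        assert out.n_samples == 8 and out.n_frames == 56

    def test_fixed_length_bypasses_optimization(self):
        series = [
            reg.RegisteredSeries(np.zeros(5 + 70), 5, "m", i, 10) for i in range(4)
        ]
        out = reg.select_time_length(series, fixed_length=51)
        assert out.n_frames == 56 and out.onset_column == 5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            reg.select_time_length([])
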