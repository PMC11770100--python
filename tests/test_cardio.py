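"""Cardiac chain: traces, filtering, peaks, geometry, indices, full analysis."""

import warnings

import numpy as np
import pytest

import zfscreen as z
from zfscreen.cardio import NoCyclesError, SegmentationError
from zfscreen.core import Trace, VideoStack

from conftest import WIDE_BAND, autocorr_period, brute_force_peaks


def constant_video(value=100.0, n=40, size=(30, 30), fs=35.0):
    return VideoStack(frames=np.full((n, *size), float(value)), frame_rate=fs)


def raised_cosine_trace(freq_hz, duration=10.0, fs=35.0, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return Trace(values=0.5 * (1 + np.cos(2 * np.pi * freq_hz * t + phase)), sampling_rate=fs)


class TestExtractRoiTrace:
    def test_constant_video_constant_trace(self):
        trace = z.extract_roi_trace(constant_video(100.0), roi=(5, 5, 10, 10))
        assert np.all(trace.values == 100.0)
        assert trace.sampling_rate == 35.0

    def test_phantom_trace_period_matches_heart_rate(self, heart_video_clean):
        video, gt = heart_video_clean
        trace = z.extract_roi_trace(video)
        period = autocorr_period(trace.values)
        assert period == pytest.approx(60.0 / gt.heart_rate * video.frame_rate, abs=1.0)

    def test_1x1_roi_is_pixel_series(self, heart_video_clean):
        video, _ = heart_video_clean
        trace = z.extract_roi_trace(video, roi=(100, 100, 1, 1))
        assert np.array_equal(trace.values, video.frames[:, 100, 100].astype(float))

    def test_roi_outside_frame_rejected(self):
        with pytest.raises(ValueError, match="roi"):
            z.extract_roi_trace(constant_video(size=(20, 20)), roi=(15, 15, 10, 10))


class TestBandpass:
    def test_passband_center_preserves_amplitude(self):
        trace = raised_cosine_trace(1.0, duration=20.0)
        out = z.bandpass(trace)
        mid = out.values[200:500]  # steady-state section
        assert np.ptp(mid) >= 0.9 * np.ptp(trace.values)

    def test_dc_is_rejected(self):
        out = z.bandpass(Trace(values=np.full(200, 100.0), sampling_rate=35.0))
        assert np.max(np.abs(out.values)) < 1e-6 * 100.0

    def test_stopband_tone_attenuated(self):
        trace = raised_cosine_trace(10.0, duration=10.0)
        out = z.bandpass(trace)
        assert np.ptp(out.values[100:250]) < 0.1 * np.ptp(trace.values)

    def test_cutoff_above_nyquist_names_limit(self):
        with pytest.raises(ValueError, match="Nyquist"):
            z.bandpass(raised_cosine_trace(1.0), low=0.2, high=20.0)


class TestNormalize:
    def test_min_max_scaling(self):
        out = z.normalize(Trace(values=np.array([2.0, 4.0, 6.0]), sampling_rate=1.0))
        assert np.allclose(out.values, [0.0, 0.5, 1.0])

    def test_idempotent_on_unit_range(self):
        trace = Trace(values=np.array([0.0, 0.25, 1.0, 0.5]), sampling_rate=1.0)
        assert np.allclose(z.normalize(trace).values, trace.values)

    def test_constant_trace_signals_no_cardiac_signal(self):
        with pytest.raises(ValueError, match="no cardiac signal"):
            z.normalize(Trace(values=np.full(50, 3.0), sampling_rate=10.0))


class TestHeartRate:
    @pytest.mark.parametrize("freq,expected", [(2.5, 150.0), (2.0, 120.0)])
    def test_known_rates_recovered_exactly(self, freq, expected):
        assert z.heart_rate(raised_cosine_trace(freq)) == pytest.approx(expected, abs=1e-6)

    @pytest.mark.parametrize("freq", [1.4, 2.0, 2.5, 3.1])
    @pytest.mark.parametrize("phase", [0.0, 1.1, 2.9])
    def test_matches_brute_force_peak_oracle(self, freq, phase):
        """scipy peak picking must agree with an exhaustive local-maximum
        scan on clean periodic traces. Maxima within half a period of the
        record ends are excluded from the set comparison (their prominence is
        truncated by the window); they can shift the interval-based rate by
        at most one sample per window, so the rates agree to 0.5 beats/min."""
        from scipy.signal import find_peaks

        trace = raised_cosine_trace(freq, phase=phase)
        oracle_peaks = brute_force_peaks(trace.values)
        period = float(np.median(np.diff(oracle_peaks)))
        n = trace.values.size

        def interior(peaks):
            return {int(p) for p in peaks if period / 2 <= p <= n - 1 - period / 2}

        impl_peaks, _ = find_peaks(trace.values, prominence=0.2, distance=7)
        assert interior(impl_peaks) == interior(oracle_peaks)

        span = (oracle_peaks[-1] - oracle_peaks[0]) / trace.sampling_rate
        oracle_hr = 60.0 * (len(oracle_peaks) - 1) / span
        assert z.heart_rate(trace) == pytest.approx(oracle_hr, abs=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError, match="2 s"):
            z.heart_rate(raised_cosine_trace(2.0, duration=1.5))

    def test_flat_trace_error_propagates_from_normalize(self):
        flat = Trace(values=np.full(200, 5.0), sampling_rate=35.0)
        with pytest.raises(ValueError, match="no cardiac signal"):
            z.heart_rate(z.normalize(z.bandpass(flat)))


class TestSegmentVentricle:
    def test_noise_free_boundary_centered_on_truth(self, heart_video_clean):
        video, gt = heart_video_clean
        edge = z.segment_ventricle(video.frames[0])
        cx, cy = edge[:, 0].mean(), edge[:, 1].mean()
        assert np.hypot(cx - gt.center[0], cy - gt.center[1]) <= 1.0

    def test_blank_frame_flagged(self):
        with pytest.raises(SegmentationError):
            z.segment_ventricle(np.full((60, 60), 200.0))

    def test_noisy_boundary_within_2px_of_true_ellipse(self):
        video, gt = z.generate_heart_video(z.HeartPhantomParams(noise_sd=10.0, seed=13))
        edge = z.segment_ventricle(video.frames[0])
        # distance from each edge point to the true ellipse, first order
        a, b = gt.d_l[0] / 2.0, gt.d_s[0] / 2.0
        dx, dy = edge[:, 0] - gt.center[0], edge[:, 1] - gt.center[1]
        g = (dx / a) ** 2 + (dy / b) ** 2
        grad = 2 * np.hypot(dx / a**2, dy / b**2)
        assert np.max(np.abs(1 - g) / grad) <= 2.0


class TestFitEllipse:
    def test_exact_conic_points_recovered_to_1e6(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        th = np.deg2rad(30.0)
        x = 90 + 75 * np.cos(t) * np.cos(th) - 50 * np.sin(t) * np.sin(th)
        y = 80 + 75 * np.cos(t) * np.sin(th) + 50 * np.sin(t) * np.cos(th)
        fit = z.fit_ellipse(np.column_stack([x, y]), pixel_size=1.0)
        assert fit.d_l == pytest.approx(150.0, abs=1e-6)
        assert fit.d_s == pytest.approx(100.0, abs=1e-6)
        assert fit.angle == pytest.approx(30.0, abs=1e-6)

    def test_circle_gives_equal_axes(self):
        t = np.linspace(0, 2 * np.pi, 60, endpoint=False)
        pts = np.column_stack([40 + 50 * np.cos(t), 40 + 50 * np.sin(t)])
        fit = z.fit_ellipse(pts)
        assert fit.d_l == pytest.approx(100.0, abs=1e-6)
        assert fit.d_s == pytest.approx(100.0, abs=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            z.fit_ellipse(np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]]))

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(ValueError):
            z.fit_ellipse(pts)

    def test_pixel_size_scales_lengths_not_fac(self):
        """Doubling µm/px doubles diameters, quadruples areas, octuples
        volumes, and leaves FAC untouched."""
        t = np.linspace(0, 2 * np.pi, 80, endpoint=False)
        pts = np.column_stack([60 + 40 * np.cos(t), 60 + 25 * np.sin(t)])
        f1 = z.fit_ellipse(pts, pixel_size=1.0)
        f2 = z.fit_ellipse(pts, pixel_size=2.0)
        assert f2.d_l == pytest.approx(2 * f1.d_l)
        assert z.area(f2.d_l, f2.d_s) == pytest.approx(4 * z.area(f1.d_l, f1.d_s))
        assert z.volume(f2.d_l, f2.d_s) == pytest.approx(8 * z.volume(f1.d_l, f1.d_s))
        fac1 = z.fac(z.area(f1.d_l, f1.d_s), 0.5 * z.area(f1.d_l, f1.d_s))
        fac2 = z.fac(z.area(f2.d_l, f2.d_s), 0.5 * z.area(f2.d_l, f2.d_s))
        assert fac1 == pytest.approx(fac2)


class TestBuildMMode:
    def test_constant_video_constant_matrix(self):
        m = z.build_mmode(constant_video(77.0), ((2.0, 15.0), (27.0, 15.0)))
        assert np.all(m.intensities == 77.0)
        assert m.intensities.shape[0] == 40

    def test_dark_width_oscillates_at_heart_rate(self, heart_video_clean):
        video, gt = heart_video_clean
        cy = (video.frames.shape[1] - 1) / 2
        m = z.build_mmode(video, ((20.0, cy), (video.frames.shape[2] - 20.0, cy)))
        dark_width = (m.intensities < 130).sum(axis=1)
        period = autocorr_period(dark_width.astype(float))
        assert abs(period - 60.0 / gt.heart_rate * video.frame_rate) <= 1.0

    def test_zero_length_line_rejected(self):
        with pytest.raises(ValueError, match="zero-length"):
            z.build_mmode(constant_video(), ((5.0, 5.0), (5.0, 5.0)))


class TestAxisTimeseries:
    def test_noise_free_axes_within_2um(self, heart_video_clean):
        video, gt = heart_video_clean
        axes = z.axis_timeseries(video)
        assert not axes.failed_frames
        assert np.max(np.abs(axes.d_l - gt.d_l)) <= 2.0
        assert np.max(np.abs(axes.d_s - gt.d_s)) <= 2.0

    def test_static_ellipse_series_constant(self):
        video, _ = z.generate_heart_video(z.HeartPhantomParams())
        static = VideoStack(
            frames=np.repeat(video.frames[:1], 30, axis=0), frame_rate=35.0, pixel_size=1.0
        )
        axes = z.axis_timeseries(static)
        assert np.ptp(axes.d_l) <= 0.5 and np.ptp(axes.d_s) <= 0.5

    def test_all_blank_video_rejected(self):
        with pytest.raises(SegmentationError, match="no usable frames"):
            z.axis_timeseries(constant_video(200.0))

    def test_rotation_changes_angle_not_axes(self):
        """Rotating the phantom ellipse moves the fitted angle but the
        recovered diameters stay put (noise-free)."""
        fits = []
        for angle in (0.0, 37.0):
            video, _ = z.generate_heart_video(z.HeartPhantomParams(angle=angle, duration=0.5))
            edge = z.segment_ventricle(video.frames[0])
            fits.append(z.fit_ellipse(edge, video.pixel_size))
        assert abs(fits[0].d_l - fits[1].d_l) <= 1.0
        assert abs(fits[0].d_s - fits[1].d_s) <= 1.0
        assert fits[1].angle == pytest.approx(37.0, abs=2.0)


class TestDetectEdEs:
    @staticmethod
    def phantom_axes(n_periods=5.0, fs=35.0, hr=150.0, phase=0.3):
        t = np.arange(int(n_periods * 60 / hr * fs)) / fs
        w = 0.5 * (1 + np.cos(2 * np.pi * hr / 60 * t + phase))
        return 100 + 50 * w, 70 + 30 * w, fs

    def test_extrema_recovered_per_cycle(self):
        d_l, d_s, fs = self.phantom_axes()
        cycles = z.detect_ed_es(d_l, d_s, fs)
        assert len(cycles) >= 3
        for c in cycles:
            assert c.ld_d == pytest.approx(150.0, abs=2.0)
            assert c.sd_s == pytest.approx(70.0, abs=2.0)
            assert c.eda >= c.esa and c.edv >= c.esv

    def test_constant_axes_no_cycles(self):
        with pytest.raises(NoCyclesError):
            z.detect_ed_es(np.full(100, 120.0), np.full(100, 80.0), 35.0)

    def test_exactly_one_full_cycle(self):
        d_l, d_s, fs = self.phantom_axes(n_periods=2.3, phase=0.9)
        cycles = z.detect_ed_es(d_l, d_s, fs)
        assert len(cycles) == 1

    def test_nan_gaps_interpolated(self):
        d_l, d_s, fs = self.phantom_axes()
        d_l[10:12] = np.nan
        d_s[40] = np.nan
        cycles = z.detect_ed_es(d_l, d_s, fs)
        assert len(cycles) >= 3


class TestScalarIndices:
    def test_hand_evaluated_examples(self):
        assert z.area(150.0, 100.0) == pytest.approx(11780.97, abs=0.01)
        assert z.fac(100.0, 50.0) == 50.0
        assert z.fac(11780.97, 5497.79) == pytest.approx(53.33, abs=0.01)
        assert z.volume(150.0, 100.0) == pytest.approx(0.7853981634, abs=1e-9)
        assert z.volume(100.0, 70.0) == pytest.approx(0.2565634000, abs=1e-9)
        assert z.stroke_volume(0.7854, 0.2566) == pytest.approx(0.5288, abs=1e-12)
        assert z.cardiac_output(0.27, 159.0) == pytest.approx(42.93, abs=1e-9)

    def test_degenerate_inputs(self):
        assert z.area(0.0, 123.0) == 0.0
        assert z.area(7.0, 7.0) == pytest.approx(np.pi * 49 / 4)
        assert z.fac(55.5, 55.5) == 0.0
        assert z.volume(50.0, 0.0) == 0.0
        assert z.stroke_volume(0.4, 0.4) == 0.0
        assert z.cardiac_output(0.0, 120.0) == 0.0

    def test_ordering_violations_rejected(self):
        with pytest.raises(ValueError):
            z.fac(50.0, 100.0)
        with pytest.raises(ValueError):
            z.stroke_volume(0.5, 0.6)


class TestAnalyze:
    def test_phantom_recovery_with_noise(self, heart_video_noisy):
        video, gt = heart_video_noisy
        report = z.analyze(video, z.CardiacConfig(band=WIDE_BAND))
        assert abs(report.hr - gt.heart_rate) <= 3.0
        assert abs(report.fac - gt.fac) <= 3.0
        assert abs(report.sv - gt.sv) <= 0.10 * gt.sv

    def test_report_identity_co_eq_sv_hr(self, heart_video_noisy):
        video, _ = heart_video_noisy
        report = z.analyze(video, z.CardiacConfig(band=WIDE_BAND))
        assert report.co == report.sv * report.hr
        assert 0.0 <= report.fac <= 100.0

    def test_band_edge_warning_when_hr_exceeds_cutoff(self, heart_video_clean):
        video, _ = heart_video_clean  # 150 bpm = 2.5 Hz vs 2 Hz default cutoff
        with pytest.warns(UserWarning, match="band edge"):
            report = z.analyze(video)
        assert "hr_near_band_edge" in report.qc

    def test_static_heart_video_rejected(self):
        video, _ = z.generate_heart_video(z.HeartPhantomParams(duration=6.0))
        static = VideoStack(
            frames=np.repeat(video.frames[:1], 210, axis=0), frame_rate=35.0, pixel_size=1.0
        )
        with pytest.raises((ValueError, NoCyclesError)):
            z.analyze(static, z.CardiacConfig(band=WIDE_BAND))
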