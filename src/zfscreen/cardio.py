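"""Cardiac quantification for larval zebrafish heart videos.

Two measurement chains run on a grayscale time-lapse of a laterally oriented
larva heart:

1. **Heart rate.** The mean gray value of a region of interest (ROI) over the
   beating ventricle oscillates with the heartbeat. The trace is band-pass
   filtered with a zero-phase Butterworth filter (default 0.2–2 Hz),
   min–max normalized, and the beat rate is estimated from the detected
   peaks: HR = 60·(n−1)/(t_last − t_first) beats/min, using the span between
   the first and last peak rather than the raw window length so a partial
   period at either end does not bias the estimate.

2. **Ventricular geometry.** Each frame is segmented (dark ventricle on a
   lighter background), an ellipse is fitted to the ventricular edge, and the
   long/short axis diameters D_L(t), D_S(t) are tracked in µm. Cardiac cycles
   are delimited by successive end-diastolic maxima of the elliptical area
   series; per cycle, the axes are read at the area maximum (end-diastole,
   ED) and minimum (end-systole, ES) and converted to the standard indices

   * Area = ¼·π·D_L·D_S                       (µm²)
   * FAC  = 100·(EDA − ESA)/EDA                (%)
   * Volume = ⅙·π·D_L·D_S²                     (µm³, reported in nL)
   * SV   = EDV − ESV                          (nL/beat)
   * CO   = SV × HR                            (nL/min)

An M-mode matrix — gray values sampled along a fixed line, one row per
frame — is available for wall-motion display and periodicity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy import signal
from skimage.filters import threshold_otsu
from skimage.measure import EllipseModel, find_contours, label, regionprops

from .core import UM3_PER_NL, Trace, VideoStack, ZfscreenError, as_gray

__all__ = [
    "MModeMatrix",
    "EllipseFit",
    "CycleMeasures",
    "CardiacReport",
    "AxisTimeseries",
    "CardiacConfig",
    "SegmentationError",
    "NoCyclesError",
    "extract_roi_trace",
    "bandpass",
    "normalize",
    "heart_rate",
    "segment_ventricle",
    "fit_ellipse",
    "build_mmode",
    "axis_timeseries",
    "detect_ed_es",
    "area",
    "fac",
    "volume",
    "stroke_volume",
    "cardiac_output",
    "analyze",
]


class SegmentationError(ZfscreenError):
    """No usable ventricle component in a frame (or in any frame)."""


class NoCyclesError(ZfscreenError):
    """The axis series does not contain one complete cardiac cycle."""


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MModeMatrix:
    """Motion-mode matrix: I[t][x] = gray value at position x along a fixed
    line in frame t, as in M-mode echocardiography."""

    intensities: np.ndarray  # (n_frames, n_samples), values in [0, 255]
    line: tuple[tuple[float, float], tuple[float, float]]  # endpoints, (x, y)
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]


@dataclass(frozen=True)
class EllipseFit:
    """Ellipse fitted to the ventricular edge; axis lengths are diameters."""

    center: tuple[float, float]  # px, (x, y)
    d_l: float  # µm, long-axis diameter
    d_s: float  # µm, short-axis diameter
    angle: float  # degrees, long axis from +x toward +y, in [0, 180)
    residual: float  # px, mean absolute orthogonal residual

    def __post_init__(self) -> None:
        if not self.d_l >= self.d_s > 0:
            raise ValueError("need d_l >= d_s > 0")


@dataclass(frozen=True)
class CycleMeasures:
    """Axis, area and volume extrema of one cardiac cycle."""

    ld_d: float  # µm, long axis at end-diastole
    ld_s: float  # µm, long axis at end-systole
    sd_d: float  # µm, short axis at end-diastole
    sd_s: float  # µm, short axis at end-systole
    eda: float  # µm²
    esa: float  # µm²
    edv: float  # nL
    esv: float  # nL
    start_frame: int
    end_frame: int


@dataclass(frozen=True)
class CardiacReport:
    """Summary cardiac indices of one recording.

    ``co == sv * hr`` holds exactly by construction; FAC is in [0, 100].
    """

    hr: float  # beats/min
    fac: float  # %
    sv: float  # nL/beat
    co: float  # nL/min
    cycles: tuple[CycleMeasures, ...]
    qc: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "hr_bpm": self.hr,
            "fac_percent": self.fac,
            "sv_nl": self.sv,
            "co_nl_per_min": self.co,
            "n_cycles": len(self.cycles),
            "cycles": [
                {
                    "ld_d_um": c.ld_d,
                    "ld_s_um": c.ld_s,
                    "sd_d_um": c.sd_d,
                    "sd_s_um": c.sd_s,
                    "eda_um2": c.eda,
                    "esa_um2": c.esa,
                    "edv_nl": c.edv,
                    "esv_nl": c.esv,
                    "start_frame": c.start_frame,
                    "end_frame": c.end_frame,
                }
                for c in self.cycles
            ],
            "qc": list(self.qc),
        }


@dataclass(frozen=True)
class AxisTimeseries:
    """Per-frame fitted axis diameters; failed frames hold NaN."""

    d_l: np.ndarray  # µm
    d_s: np.ndarray  # µm
    sampling_rate: float
    failed_frames: tuple[int, ...] = ()


@dataclass(frozen=True)
class CardiacConfig:
    """Tunable parameters of the full analysis chain."""

    roi: tuple[int, int, int, int] | None = None  # (x, y, w, h); None = full frame
    band: tuple[float, float] = (0.2, 2.0)  # Hz, Butterworth pass band
    filter_order: int = 4
    min_prominence: float = 0.2  # on the normalized trace
    min_separation: float = 0.2  # s, between counted peaks
    threshold: float | None = None  # segmentation threshold; None = Otsu
    smooth_sigma: float = 1.0  # px, pre-segmentation Gaussian blur
    roi_hint: tuple[int, int, int, int] | None = None  # restrict segmentation


# --------------------------------------------------------------------------
# intensity-trace chain
# --------------------------------------------------------------------------


def extract_roi_trace(video: VideoStack, roi: tuple[int, int, int, int] | None = None) -> Trace:
    """Mean gray value of a rectangular ROI per frame.

    ``roi`` is (x, y, w, h); None averages the whole frame. Sampling rate is
    the video frame rate.
    """
    frames = video.frames
    if roi is not None:
        x, y, w, h = roi
        _, fh, fw = frames.shape
        if w <= 0 or h <= 0 or x < 0 or y < 0 or x + w > fw or y + h > fh:
            raise ValueError(f"roi {roi} outside {fw}x{fh} frame bounds")
        frames = frames[:, y : y + h, x : x + w]
    return Trace(values=frames.mean(axis=(1, 2)), sampling_rate=video.frame_rate)


def bandpass(trace: Trace, low: float = 0.2, high: float = 2.0, order: int = 4) -> Trace:
    """Zero-phase Butterworth band-pass filter (forward–backward).

    Defaults follow the 0.2–2 Hz heart-signal band; note that 2 Hz
    corresponds to 120 beats/min, so override ``high`` for faster hearts.
    """
    nyquist = trace.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency {nyquist:g} Hz"
        )
    b, a = signal.butter(order, [low, high], btype="bandpass", fs=trace.sampling_rate)
    # Remove the DC level up front and use Gustafsson's forward-backward edge
    # handling: the filter's slow poles (~1/low time constant) otherwise ring
    # at the record boundaries and swamp short recordings.
    values = trace.values - trace.values.mean()
    return Trace(
        values=signal.filtfilt(b, a, values, method="gust"), sampling_rate=trace.sampling_rate
    )


def normalize(trace: Trace) -> Trace:
    """Min–max scale a trace to [0, 1]; a flat trace has no cardiac signal."""
    lo, hi = float(trace.values.min()), float(trace.values.max())
    if hi - lo <= 1e-12 * max(abs(hi), 1.0):
        raise ValueError("constant trace: no cardiac signal to normalize")
    return Trace(values=(trace.values - lo) / (hi - lo), sampling_rate=trace.sampling_rate)


def _find_beat_peaks(trace: Trace, min_prominence: float, min_separation: float) -> np.ndarray:
    distance = max(1, int(round(min_separation * trace.sampling_rate)))
    peaks, _ = signal.find_peaks(trace.values, prominence=min_prominence, distance=distance)
    return peaks


def heart_rate(trace: Trace, min_prominence: float = 0.2, min_separation: float = 0.2) -> float:
    """Heart rate in beats/min from peaks of a filtered, normalized trace.

    Peaks need prominence ≥ ``min_prominence`` and separation ≥
    ``min_separation`` s; the rate is 60·(n−1)/(t_last − t_first), i.e. the
    count of full inter-peak intervals over the time they span.
    """
    if trace.duration < 2.0:
        raise ValueError("trace shorter than 2 s: insufficient support for a rate")
    peaks = _find_beat_peaks(trace, min_prominence, min_separation)
    if peaks.size < 2:
        raise ValueError("fewer than two beat peaks detected; no rate estimate")
    span = (peaks[-1] - peaks[0]) / trace.sampling_rate
    return 60.0 * (peaks.size - 1) / span


# --------------------------------------------------------------------------
# geometry chain
# --------------------------------------------------------------------------


def segment_ventricle(
    frame: np.ndarray,
    roi_hint: tuple[int, int, int, int] | None = None,
    threshold: float | None = None,
    smooth_sigma: float = 1.0,
) -> np.ndarray:
    """Edge points of the ventricle in one frame, as an (n, 2) (x, y) array.

    Smooths, thresholds (dark object; None = Otsu), keeps the largest
    connected component within the ROI hint, and returns the sub-pixel
    iso-intensity contour of that component at the threshold level.
    """
    img = as_gray(frame)
    x0 = y0 = 0
    if roi_hint is not None:
        x0, y0, w, h = roi_hint
        img = img[y0 : y0 + h, x0 : x0 + w]
        if img.size == 0:
            raise SegmentationError("roi hint outside the frame")
    smoothed = ndi.gaussian_filter(img, smooth_sigma) if smooth_sigma > 0 else img
    if threshold is None:
        if np.ptp(smoothed) < 1.0:
            raise SegmentationError("featureless frame: no ventricle component")
        threshold = float(threshold_otsu(smoothed))
    mask = smoothed < threshold
    labels = label(mask)
    if labels.max() == 0:
        raise SegmentationError("no component below threshold")
    regions = regionprops(labels)
    biggest = max(regions, key=lambda r: r.area)

    contours = find_contours(smoothed, level=threshold)
    if not contours:
        raise SegmentationError("no closed edge at the threshold level")
    cy, cx = biggest.centroid
    best = min(
        contours,
        key=lambda c: np.hypot(c[:, 0].mean() - cy, c[:, 1].mean() - cx),
    )
    # contours are (row, col); convert to (x, y) in full-frame coordinates
    return np.column_stack([best[:, 1] + x0, best[:, 0] + y0])


def fit_ellipse(points: np.ndarray, pixel_size: float = 1.0) -> EllipseFit:
    """Least-squares conic fit of edge points, constrained to an ellipse.

    Needs at least 5 non-collinear points; axis diameters are returned in µm
    with D_L ≥ D_S enforced by swapping (and rotating the angle by 90°).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 5:
        raise ValueError("need at least 5 (x, y) points for an ellipse fit")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("degenerate point set: ellipse fit failed")
    (xc, yc) = model.center
    a, b = model.axis_lengths  # semi-axes
    theta = np.rad2deg(model.theta)
    if b > a:
        a, b = b, a
        theta += 90.0
    residual = float(np.abs(model.residuals(pts)).mean())
    return EllipseFit(
        center=(float(xc), float(yc)),
        d_l=2.0 * a * pixel_size,
        d_s=2.0 * b * pixel_size,
        angle=float(theta % 180.0),
        residual=residual,
    )


def build_mmode(
    video: VideoStack,
    line: tuple[tuple[float, float], tuple[float, float]],
    spacing: float = 1.0,
) -> MModeMatrix:
    """Sample gray values along a fixed line in every frame.

    Returns the matrix I with I[t][x] the (bilinearly interpolated) intensity
    at position x along the line in frame t, clipped to [0, 255].
    """
    (x0, y0), (x1, y1) = line
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length <= 0:
        raise ValueError("line endpoints coincide: zero-length M-mode line")
    n_samples = int(np.floor(length / spacing)) + 1
    ts = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + ts * (x1 - x0)
    ys = y0 + ts * (y1 - y0)
    rows = np.empty((video.n_frames, n_samples))
    for i in range(video.n_frames):
        rows[i] = ndi.map_coordinates(
            video.frames[i].astype(float), [ys, xs], order=1, mode="nearest"
        )
    return MModeMatrix(
        intensities=np.clip(rows, 0, 255),
        line=((float(x0), float(y0)), (float(x1), float(y1))),
        frame_rate=video.frame_rate,
    )


def axis_timeseries(
    video: VideoStack,
    roi_hint: tuple[int, int, int, int] | None = None,
    threshold: float | None = None,
    smooth_sigma: float = 1.0,
) -> AxisTimeseries:
    """Fitted long/short axis diameters per frame, in µm.

    Frames where segmentation or fitting fails carry NaN and are listed in
    ``failed_frames``; an error is raised only when no frame is usable.
    """
    n = video.n_frames
    d_l = np.full(n, np.nan)
    d_s = np.full(n, np.nan)
    failed = []
    for i in range(n):
        try:
            edge = segment_ventricle(
                video.frames[i], roi_hint=roi_hint, threshold=threshold, smooth_sigma=smooth_sigma
            )
            fit = fit_ellipse(edge, pixel_size=video.pixel_size)
        except (SegmentationError, ValueError):
            failed.append(i)
            continue
        d_l[i], d_s[i] = fit.d_l, fit.d_s
    if len(failed) == n:
        raise SegmentationError("no usable frames: ventricle never segmented")
    return AxisTimeseries(
        d_l=d_l, d_s=d_s, sampling_rate=video.frame_rate, failed_frames=tuple(failed)
    )


def _interp_nan(values: np.ndarray) -> np.ndarray:
    out = values.copy()
    bad = np.isnan(out)
    if bad.any():
        idx = np.arange(out.size)
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out


def detect_ed_es(
    d_l: np.ndarray,
    d_s: np.ndarray,
    sampling_rate: float,
    min_separation: float = 0.2,
    smooth_sigma_s: float = 0.06,
) -> list[CycleMeasures]:
    """Split the axis series into cardiac cycles and measure ED/ES extrema.

    Cycles are delimited by successive maxima of the (lightly smoothed)
    elliptical area series ¼πD_L·D_S; within each cycle end-diastole is the
    area maximum and end-systole the area minimum, and the long/short axes
    are read at those two frames so both diameters refer to a common instant.
    """
    d_l = _interp_nan(np.asarray(d_l, dtype=float))
    d_s = _interp_nan(np.asarray(d_s, dtype=float))
    if d_l.shape != d_s.shape or d_l.ndim != 1:
        raise ValueError("d_l and d_s must be 1-D arrays of equal length")
    a_raw = np.pi / 4.0 * d_l * d_s
    span = float(np.ptp(a_raw))
    if span <= 1e-9 * max(abs(a_raw).max(), 1.0):
        raise NoCyclesError("area series is constant: no cardiac cycles")
    a_smooth = ndi.gaussian_filter1d(a_raw, max(smooth_sigma_s * sampling_rate, 0.5))
    distance = max(1, int(round(min_separation * sampling_rate)))
    maxima, _ = signal.find_peaks(a_smooth, prominence=0.2 * span, distance=distance)
    if maxima.size < 2:
        raise NoCyclesError("fewer than one complete cardiac cycle detected")

    cycles = []
    for start, end in zip(maxima[:-1], maxima[1:]):
        seg = slice(start, end + 1)
        ed = start + int(np.argmax(a_raw[seg]))
        es = start + int(np.argmin(a_raw[seg]))
        ld_d, sd_d = float(d_l[ed]), float(d_s[ed])
        ld_s, sd_s = float(d_l[es]), float(d_s[es])
        cycles.append(
            CycleMeasures(
                ld_d=ld_d,
                ld_s=ld_s,
                sd_d=sd_d,
                sd_s=sd_s,
                eda=area(ld_d, sd_d),
                esa=area(ld_s, sd_s),
                edv=volume(ld_d, sd_d),
                esv=volume(ld_s, sd_s),
                start_frame=int(start),
                end_frame=int(end),
            )
        )
    return cycles


# --------------------------------------------------------------------------
# scalar indices
# --------------------------------------------------------------------------


def area(d_l: float, d_s: float) -> float:
    """Elliptical ventricular area ¼·π·D_L·D_S, in µm²."""
    if d_l < 0 or d_s < 0:
        raise ValueError("axis diameters must be non-negative")
    return np.pi / 4.0 * d_l * d_s


def fac(eda: float, esa: float) -> float:
    """Fractional area change 100·(EDA − ESA)/EDA, in percent."""
    if eda <= 0:
        raise ValueError("EDA must be positive")
    if esa > eda:
        raise ValueError("ESA exceeds EDA: end-diastole/end-systole mis-ordered")
    if esa < 0:
        raise ValueError("ESA must be non-negative")
    return 100.0 * (eda - esa) / eda


def volume(d_l: float, d_s: float) -> float:
    """Prolate-ellipsoid ventricular volume ⅙·π·D_L·D_S², in nL."""
    if d_l < 0 or d_s < 0:
        raise ValueError("axis diameters must be non-negative")
    return np.pi / 6.0 * d_l * d_s**2 / UM3_PER_NL


def stroke_volume(edv: float, esv: float) -> float:
    """Stroke volume EDV − ESV, in nL/beat."""
    if esv > edv:
        raise ValueError("ESV exceeds EDV: volumes mis-ordered")
    return edv - esv


def cardiac_output(sv: float, hr: float) -> float:
    """Cardiac output SV × HR, in nL/min."""
    if sv < 0 or hr < 0:
        raise ValueError("SV and HR must be non-negative")
    return sv * hr


# --------------------------------------------------------------------------
# full analysis
# --------------------------------------------------------------------------


def analyze(video: VideoStack, config: CardiacConfig | None = None) -> CardiacReport:
    """Full cardiac phenotyping of one recording.

    Runs the intensity chain (ROI trace → band-pass → normalize → HR) and the
    geometry chain (per-frame ellipse axes → cycle ED/ES extrema → FAC, SV),
    then combines CO = mean SV × HR. Per-cycle indices are averaged over all
    complete cycles; incomplete terminal cycles are discarded by
    construction. QC flags record dropped frames, skipped cycles, and an HR
    estimate near the upper band edge (where the filter attenuates the
    signal and the band should be widened).
    """
    cfg = config or CardiacConfig()
    qc: list[str] = []

    trace = extract_roi_trace(video, cfg.roi)
    # Dominant raw-trace frequency, checked against the pass band before
    # filtering: a beat faster than the high cutoff would not merely be
    # attenuated, it could be missed entirely.
    freqs, power = signal.periodogram(trace.values - trace.values.mean(), trace.sampling_rate)
    dominant = float(freqs[np.argmax(power)]) if power.size else 0.0
    if dominant > 0.9 * cfg.band[1]:
        warnings.warn(
            f"dominant trace frequency {dominant:.2f} Hz ({dominant * 60:.0f} beats/min) is at "
            f"or above the {cfg.band[1]} Hz band edge; consider raising the high cutoff",
            stacklevel=2,
        )
        qc.append("hr_near_band_edge")
    filtered = bandpass(trace, cfg.band[0], cfg.band[1], cfg.filter_order)
    normalized = normalize(filtered)
    hr = heart_rate(normalized, cfg.min_prominence, cfg.min_separation)

    axes = axis_timeseries(
        video, roi_hint=cfg.roi_hint, threshold=cfg.threshold, smooth_sigma=cfg.smooth_sigma
    )
    if axes.failed_frames:
        qc.append(f"dropped_frames:{len(axes.failed_frames)}")
    cycles = detect_ed_es(axes.d_l, axes.d_s, axes.sampling_rate, cfg.min_separation)

    facs, svs, kept = [], [], []
    for c in cycles:
        if c.esv > c.edv:
            qc.append(f"skipped_cycle:{c.start_frame}")
            continue
        facs.append(fac(c.eda, c.esa))
        svs.append(stroke_volume(c.edv, c.esv))
        kept.append(c)
    if not kept:
        raise NoCyclesError("every detected cycle failed the volume-ordering check")

    mean_fac = float(np.mean(facs))
    mean_sv = float(np.mean(svs))
    return CardiacReport(
        hr=hr,
        fac=mean_fac,
        sv=mean_sv,
        co=cardiac_output(mean_sv, hr),
        cycles=tuple(kept),
        qc=tuple(qc),
    )
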