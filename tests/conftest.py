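"""Shared fixtures: phantoms rendered once per session and reused."""

import numpy as np
import pytest

import zfscreen as z

# Band override used whenever phantoms span the full physiological HR range
# (the default 0.2-2 Hz band tops out at 120 beats/min).
WIDE_BAND = (0.5, 5.0)


@pytest.fixture(scope="session")
def heart_video_clean():
    """Noise-free default heart phantom (150 bpm, 35 fps, 10 s) + truth."""
    return z.generate_heart_video(z.HeartPhantomParams())


@pytest.fixture(scope="session")
def heart_video_noisy():
    """Default heart phantom with moderate pixel noise."""
    return z.generate_heart_video(z.HeartPhantomParams(noise_sd=5.0, seed=3))


@pytest.fixture(scope="session")
def larva_frame_clean():
    """Noise-free head-forward larva phantom frame + truth."""
    return z.generate_larva_frame(z.LarvaPhantomParams())


def small_heart_params(**kw):
    """A compact, fast-to-render heart phantom used by batch tests."""
    defaults = dict(
        duration=6.0,
        image_size=(120, 120),
        ld_d=100.0,
        ld_s=70.0,
        sd_d=70.0,
        sd_s=50.0,
        heart_rate=120.0,
    )
    defaults.update(kw)
    return z.HeartPhantomParams(**defaults)


def brute_force_peaks(values: np.ndarray) -> np.ndarray:
    """All local maxima of a 1-D array by exhaustive scan (plateaus count
    once, at the left-middle sample). Independent oracle for peak counting."""
    peaks = []
    n = len(values)
    i = 1
    while i < n - 1:
        if values[i] > values[i - 1]:
            j = i
            while j + 1 < n and values[j + 1] == values[j]:
                j += 1
            if j < n - 1 and values[j + 1] < values[j]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return np.asarray(peaks, dtype=int)


def autocorr_period(values: np.ndarray) -> int:
    """Dominant period in samples from the first autocorrelation peak."""
    x = np.asarray(values, dtype=float)
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    peaks = brute_force_peaks(ac)
    if peaks.size == 0:
        raise ValueError("no autocorrelation peak: aperiodic signal")
    return int(peaks[np.argmax(ac[peaks])]) if ac[peaks].max() > 0 else int(peaks[0])
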