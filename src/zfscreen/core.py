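"""Shared containers and image/video IO.

Conventions used throughout the package
---------------------------------------
* Pixel coordinates are 0-based, ``x`` rightward (column index), ``y``
  downward (row index). Points are ``(x, y)`` pairs.
* Angles are in degrees, measured from the +x axis toward +y.
* Lengths are µm, areas µm², volumes nL (1 nL = 1e6 µm³), heart rate
  beats/min, cardiac output nL/min.
* Grayscale images are 2-D arrays with values in [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

UM3_PER_NL = 1e6  # 1 nL = 1e6 µm³


class ZfscreenError(Exception):
    """Base class for errors raised by this package."""


@dataclass(frozen=True)
class VideoStack:
    """An ordered stack of grayscale frames with acquisition metadata.

    Attributes
    ----------
    frames : ndarray, shape (T, H, W)
        Grayscale frames, values in [0, 255].
    frame_rate : float
        Acquisition rate in frames/s.
    pixel_size : float
        Physical size of one pixel in µm/px.
    """

    frames: np.ndarray
    frame_rate: float
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError(f"frames must be a (T, H, W) array, got shape {frames.shape}")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        """Record length in seconds (n_frames / frame_rate)."""
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class Trace:
    """A 1-D intensity time series sampled at a fixed rate."""

    values: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if not np.all(np.isfinite(values)):
            raise ValueError("trace values must be finite")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", values)

    @property
    def duration(self) -> float:
        return self.values.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sampling_rate


def as_gray(image: np.ndarray) -> np.ndarray:
    """Coerce an image array to 2-D float grayscale (RGB collapsed by mean)."""
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    return arr.astype(float)


def read_image(path: str | Path) -> np.ndarray:
    """Read a single grayscale frame from PNG/TIFF."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim == 3 and arr.shape[-1] not in (3, 4):
            arr = arr[0]  # first page of a stack
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    return as_gray(arr)


def read_video(path: str | Path, frame_rate: float, pixel_size: float = 1.0) -> VideoStack:
    """Read a multi-page TIFF or common video container as a VideoStack.

    Frame rate and pixel size are not reliably stored in these containers and
    must be supplied by the caller.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
    else:
        import imageio.v3 as iio

        frames = [as_gray(f) for f in iio.imiter(path)]
        if not frames:
            raise ValueError(f"no frames in {path}")
        arr = np.stack(frames)
    if arr.ndim == 4:  # RGB pages
        arr = arr[..., :3].mean(axis=-1)
    return VideoStack(frames=arr.astype(float), frame_rate=frame_rate, pixel_size=pixel_size)


def write_video(path: str | Path, video: VideoStack) -> None:
    """Write a VideoStack as an 8-bit multi-page TIFF."""
    frames = np.clip(np.round(video.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(Path(path), frames, photometric="minisblack")
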