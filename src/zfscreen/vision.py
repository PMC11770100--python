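"""Computer-vision chain for larva handling: presence detection, eye
segmentation, head/tail orientation, and per-frame coordinate tracking.

The larva and its eyes are dark objects on a lighter background
(bright-field convention); a polarity flag inverts this. The orientation
decision projects the mean eye position and the body centroid onto the
channel axis: the call is head-forward when the eyes lead the body centroid
along +axis by more than a dead-band, tail-forward when they trail it, and
undetermined inside the dead-band or when no eyes are found. The mapping
from segmented eye features to a direction is this package's own rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import dilation, disk, erosion

from .core import VideoStack, as_gray

__all__ = [
    "DetectionResult",
    "OrientationCall",
    "Trajectory",
    "MorphologyConfig",
    "detect_larva",
    "segment_eyes",
    "determine_orientation",
    "track",
]


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of larva presence detection on one frame."""

    present: bool
    box: tuple[int, int, int, int] | None = None  # (x, y, w, h)
    area: float = 0.0  # px²
    centroid: tuple[float, float] | None = None  # (x, y)


@dataclass(frozen=True)
class OrientationCall:
    """Head/tail direction decision for a larva in the channel."""

    orientation: str  # head_forward | tail_forward | undetermined
    eye_centroids: tuple[tuple[float, float], ...] = ()
    body_centroid: tuple[float, float] | None = None
    axis_angle: float = 0.0  # degrees


@dataclass(frozen=True)
class Trajectory:
    """Per-frame larva positions; frames without a detection are absent."""

    entries: tuple[tuple[int, tuple[float, float] | None, bool], ...]

    def __len__(self) -> int:
        return len(self.entries)

    def positions(self) -> np.ndarray:
        """(x, y) positions of present frames as an (n, 2) array."""
        return np.array([c for _, c, p in self.entries if p], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class MorphologyConfig:
    """Settings of the eye-segmentation chain.

    The chain is median filter → binarize → erosion → dilation; the named
    kernel sizes and gates are free parameters of the method (the operations
    themselves are standard) and every one can be overridden.
    """

    median_size: int = 3  # median filter kernel, px
    threshold: float | None = None  # None = darkest class of a 3-class Otsu
    selem_radius: int = 1  # elliptical structuring element radius
    erosion_iterations: int = 1
    dilation_iterations: int = 1
    min_area: float = 5.0  # px², reject specks
    max_area: float = 400.0  # px², reject body fragments
    min_circularity: float = 0.5  # 4πA/P², reject elongated residue
    max_eyes: int = 2
    dark_objects: bool = True  # polarity: features darker than background


def _binarize(image: np.ndarray, threshold: float | None, dark_objects: bool) -> np.ndarray:
    if threshold is None:
        threshold = threshold_otsu(image)
    return image < threshold if dark_objects else image > threshold


def detect_larva(
    image: np.ndarray,
    threshold: float | None = None,
    min_area: float = 50.0,
    dark_objects: bool = True,
) -> DetectionResult:
    """Decide whether a larva is in the field of view.

    Smooth with a small blur, binarize (None threshold = Otsu), and take
    connected components; the larva is present iff the largest component is
    at least ``min_area`` px².
    """
    img = as_gray(image)
    if min_area <= 0:
        raise ValueError("min_area must be positive")
    smoothed = ndi.uniform_filter(img, size=3)
    if threshold is None and np.ptp(smoothed) < 1.0:
        return DetectionResult(present=False)  # featureless frame, Otsu undefined
    mask = _binarize(smoothed, threshold, dark_objects)
    labels = label(mask)
    if labels.max() == 0:
        return DetectionResult(present=False)
    regions = regionprops(labels)
    biggest = max(regions, key=lambda r: r.area)
    if biggest.area < min_area:
        return DetectionResult(present=False)
    r0, c0, r1, c1 = biggest.bbox
    cy, cx = biggest.centroid
    return DetectionResult(
        present=True,
        box=(int(c0), int(r0), int(c1 - c0), int(r1 - r0)),
        area=float(biggest.area),
        centroid=(float(cx), float(cy)),
    )


def segment_eyes(image: np.ndarray, config: MorphologyConfig | None = None) -> list[tuple[float, float]]:
    """Segment the eye blobs and return their centroids (at most two).

    Applies median filter → binarize → erosion → dilation, then keeps the
    darkest compact components passing the area and circularity gates, sorted
    by area descending. An empty list is a valid return (no eyes visible).
    By default the binarization threshold is the lower cut of a 3-class Otsu,
    which separates the eyes from both the body and the background.
    """
    cfg = config or MorphologyConfig()
    img = as_gray(image)
    filtered = ndi.median_filter(img, size=cfg.median_size)

    threshold = cfg.threshold
    if threshold is None:
        try:
            cuts = threshold_multiotsu(filtered.astype(np.uint8), classes=3)
        except ValueError:  # fewer than 3 gray levels present
            return []
        threshold = float(cuts[0]) if cfg.dark_objects else float(cuts[-1])
    mask = _binarize(filtered, threshold, cfg.dark_objects)

    selem = disk(cfg.selem_radius)
    for _ in range(cfg.erosion_iterations):
        mask = erosion(mask, selem)
    for _ in range(cfg.dilation_iterations):
        mask = dilation(mask, selem)

    candidates = []
    for region in regionprops(label(mask)):
        if not (cfg.min_area <= region.area <= cfg.max_area):
            continue
        perimeter = max(region.perimeter, 1e-9)
        circularity = 4.0 * np.pi * region.area / perimeter**2
        if circularity < cfg.min_circularity:
            continue
        cy, cx = region.centroid
        candidates.append((region.area, (float(cx), float(cy))))
    candidates.sort(key=lambda t: -t[0])
    return [c for _, c in candidates[: cfg.max_eyes]]


def determine_orientation(
    eyes: "list[tuple[float, float]]",
    body: tuple[float, float],
    axis_angle: float,
    dead_band: float = 2.0,
    max_inter_eye: float | None = None,
) -> OrientationCall:
    """Decide head-forward vs tail-forward from eye and body positions.

    Projects the mean eye position and the body centroid onto the channel
    axis unit vector (cos θ, sin θ); head_forward iff the eyes lead by more
    than ``dead_band`` px, tail_forward iff they trail by more, otherwise
    undetermined. No eyes, or an implausibly wide eye pair (when
    ``max_inter_eye`` is set), also yields undetermined.
    """
    if body is None:
        raise ValueError("body centroid is required")
    eyes = list(eyes)
    call = lambda o: OrientationCall(  # noqa: E731
        orientation=o,
        eye_centroids=tuple(eyes),
        body_centroid=tuple(body),
        axis_angle=axis_angle,
    )
    if not eyes:
        return call("undetermined")
    if max_inter_eye is not None and len(eyes) == 2:
        d = np.hypot(eyes[0][0] - eyes[1][0], eyes[0][1] - eyes[1][1])
        if d > max_inter_eye:
            return call("undetermined")
    th = np.deg2rad(axis_angle)
    u = np.array([np.cos(th), np.sin(th)])
    lead = float(np.dot(np.mean(np.asarray(eyes, dtype=float), axis=0) - np.asarray(body, dtype=float), u))
    if lead > dead_band:
        return call("head_forward")
    if lead < -dead_band:
        return call("tail_forward")
    return call("undetermined")


def track(
    video: VideoStack,
    threshold: float | None = None,
    min_area: float = 50.0,
    dark_objects: bool = True,
) -> Trajectory:
    """Per-frame larva centroid tracking (pure measurement, no motion model)."""
    entries = []
    for i in range(video.n_frames):
        det = detect_larva(video.frames[i], threshold=threshold, min_area=min_area, dark_objects=dark_objects)
        entries.append((i, det.centroid, det.present))
    return Trajectory(entries=tuple(entries))
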