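"""Video preprocessing: from an (experiment, background) pair to a trajectory.

Reproduces the four-stage segmentation pipeline for overhead open-field
video: spatial binning, x,y alignment of the empty-arena background clip to
the experiment clip, background subtraction, automatic Minimum-method
thresholding, morphological anti-aliasing (opening), and per-frame blob
tracking of the single largest in-range connected component.

Frames are 8-bit greyscale throughout; masks are boolean.  The background
model is the temporal median of the background clip, which is robust to
transient noise in the ~10 s empty-arena recording.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .model import ArenaGeometry, Trajectory

__all__ = [
    "FrameStack",
    "BinaryStack",
    "spatial_bin",
    "detect_arena",
    "align_background",
    "subtract_background",
    "threshold_minimum",
    "antialias",
    "track_blobs",
    "preprocess_pair",
]


@dataclass
class FrameStack:
    """An ordered stack of greyscale frames with a frame rate.

    ``frames`` is a ``(n, height, width)`` uint8 array.
    """

    frames: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.frames.dtype != np.uint8:
            self.frames = np.clip(np.round(self.frames), 0, 255).astype(np.uint8)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]


@dataclass
class BinaryStack:
    """An ordered stack of boolean foreground masks."""

    frames: np.ndarray
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, height, width) array")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def spatial_bin(stack: FrameStack, factor: int) -> FrameStack:
    """Bin each frame by ``factor`` in both axes, averaging each block.

    Dimensions must divide evenly; otherwise the error names the padding
    that would be required.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    if factor == 1:
        return stack
    n, h, w = stack.frames.shape
    if h % factor or w % factor:
        pad_h = (-h) % factor
        pad_w = (-w) % factor
        raise ValueError(
            f"frame size {w}x{h} not divisible by {factor}; "
            f"pad to {w + pad_w}x{h + pad_h} first"
        )
    binned = (
        stack.frames.reshape(n, h // factor, factor, w // factor, factor)
        .mean(axis=(2, 4))
    )
    return FrameStack(binned, stack.frame_rate)


def detect_arena(frame: np.ndarray, min_fill: float = 0.92) -> ArenaGeometry:
    """Locate the circular arena floor (bright disc on dark surround).

    Thresholds the frame midway between its darkest and brightest
    intensities, takes the largest connected bright region and fits a circle
    through its centroid and area.  The region must fill at least
    ``min_fill`` of its fitted circle, otherwise no credible circular
    structure is present and an error is raised.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lo, hi = frame.min(), frame.max()
    if hi - lo < 10:  # essentially flat: no structure
        raise ValueError("no circular arena detected: frame has no contrast")
    mask = frame > (lo + hi) / 2.0
    labels = measure.label(mask)
    if labels.max() == 0:
        raise ValueError("no circular arena detected: no bright region")
    props = max(measure.regionprops(labels), key=lambda p: p.area)
    cy, cx = props.centroid
    radius = float(np.sqrt(props.area / np.pi))
    yy, xx = np.ogrid[: frame.shape[0], : frame.shape[1]]
    circle = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    overlap = np.logical_and(circle, labels == props.label).sum() / circle.sum()
    if overlap < min_fill:
        raise ValueError(
            f"no circular arena detected: best region fills only "
            f"{overlap:.0%} of its fitted circle"
        )
    return ArenaGeometry(centre_x=float(cx), centre_y=float(cy), radius=radius)


def _median_frame(stack: FrameStack) -> np.ndarray:
    return np.median(stack.frames, axis=0)


def align_background(experiment: FrameStack, background: FrameStack) -> FrameStack:
    """Translate the background clip so the arenas of both clips coincide.

    Arena centres are detected in the temporal-median frame of each clip and
    the background is shifted by the rounded integer centre difference.
    Regions shifted in from outside the frame take the nearest edge value.
    """
    if experiment.frames.shape[1:] != background.frames.shape[1:]:
        raise ValueError("experiment and background frame sizes differ")
    exp_arena = detect_arena(_median_frame(experiment))
    bg_arena = detect_arena(_median_frame(background))
    dx = int(round(exp_arena.centre_x - bg_arena.centre_x))
    dy = int(round(exp_arena.centre_y - bg_arena.centre_y))
    if dx == 0 and dy == 0:
        return background
    shifted = np.empty_like(background.frames)
    for i, frame in enumerate(background.frames):
        shifted[i] = ndi.shift(frame, (dy, dx), order=0, mode="nearest")
    return FrameStack(shifted, background.frame_rate)


def subtract_background(experiment: FrameStack, aligned_bg: FrameStack) -> FrameStack:
    """Absolute difference of each experiment frame from the background model.

    The background model is the temporal median of the aligned background
    clip, so the moving animal is the only persistent bright structure in
    the result.
    """
    if experiment.frames.shape[1:] != aligned_bg.frames.shape[1:]:
        raise ValueError("experiment and background frame sizes differ")
    model = _median_frame(aligned_bg)
    diff = np.abs(experiment.frames.astype(np.int16) - model.astype(np.int16))
    return FrameStack(diff.astype(np.uint8), experiment.frame_rate)


def _local_maxima(hist: np.ndarray) -> list[int]:
    """Indices of local maxima, plateau-aware (first index of each plateau)."""
    maxima: list[int] = []
    direction = 1
    for i in range(hist.shape[0] - 1):
        if direction > 0:
            if hist[i + 1] < hist[i]:
                direction = -1
                maxima.append(i)
        else:
            if hist[i + 1] > hist[i]:
                direction = 1
    return maxima


def minimum_threshold_value(counts: np.ndarray, max_iter: int = 10000) -> float:
    """Threshold intensity by the histogram-Minimum method.

    The 256-bin histogram is repeatedly smoothed with a 3-bin running mean
    until at most two local maxima remain; the threshold is the minimum of
    the smoothed histogram between them.  The histogram is padded with one
    empty bin at each end first so a mode sitting at intensity 0 or 255 —
    typical for the background peak of a subtracted video — still counts as
    a maximum.  Raises ``ValueError`` if the histogram never becomes
    bimodal (e.g. constant frames).
    """
    smooth = np.concatenate(([0.0], np.asarray(counts, dtype=np.float64), [0.0]))
    for _ in range(max_iter):
        smooth = ndi.uniform_filter1d(smooth, 3)
        maxima = _local_maxima(smooth)
        if len(maxima) == 2:
            lo, hi = maxima
            return float(lo + np.argmin(smooth[lo : hi + 1]) - 1)  # unpad
        if len(maxima) < 2:
            break
    raise ValueError(
        "thresholding failed: intensity histogram never became bimodal; "
        "increase object/background contrast or adjust stop_epsilon "
        "downstream"
    )


def threshold_minimum(stack: FrameStack, max_iter: int = 10000) -> BinaryStack:
    """Binarise with a single global Minimum-method threshold per video.

    One threshold is computed from the intensity histogram pooled over all
    frames (see :func:`minimum_threshold_value`); pixels strictly above it
    become foreground.
    """
    counts, _ = np.histogram(stack.frames, bins=256, range=(0, 256))
    thresh = minimum_threshold_value(counts, max_iter)
    return BinaryStack(stack.frames > thresh, stack.frame_rate)


def antialias(stack: BinaryStack, iterations: int = 1) -> BinaryStack:
    """Morphological opening (erode then dilate) with a 3x3 element.

    Removes speckle smaller than the structuring element — droppings,
    compression artefacts — while leaving large convex blobs essentially
    unchanged.
    """
    footprint = np.ones((3, 3), dtype=bool)
    out = stack.frames
    for _ in range(iterations):
        eroded = np.stack([ndi.binary_erosion(f, footprint) for f in out])
        out = np.stack([ndi.binary_dilation(f, footprint) for f in eroded])
    return BinaryStack(out, stack.frame_rate)


def _frame_centroid(
    mask: np.ndarray, min_area: float, max_area: float
) -> tuple[float, float] | None:
    """Centroid of the largest in-range component, or None if no candidate.

    Ties on area break toward the component with the lowest (x, y), taken
    lexicographically on the centroid.
    """
    labels = measure.label(mask)
    best = None
    for p in measure.regionprops(labels):
        if not (min_area <= p.area <= max_area):
            continue
        cy, cx = p.centroid
        key = (-p.area, cx, cy)
        if best is None or key < best[0]:
            best = (key, (cx, cy))
    return None if best is None else best[1]


def track_blobs(
    stack: BinaryStack,
    min_area: float = 50.0,
    max_area: float = 5000.0,
    max_step: float = 50.0,
    max_gap: int = 5,
) -> Trajectory:
    """Assemble the animal's trajectory from a binary stack.

    Per frame, the largest connected component with area in
    ``[min_area, max_area]`` is taken as the animal and its centroid
    recorded.  Consecutive centroids further apart than ``max_step`` pixels
    break the track, as do runs of more than ``max_gap`` empty frames;
    shorter gaps are bridged by linear interpolation of the centroid.  Of
    the resulting contiguous tracks the longest wins.  More than half the
    frames empty means tracking failed.
    """
    if min_area >= max_area:
        raise ValueError("min_area must be < max_area")
    n = stack.n_frames
    centroids: list[tuple[float, float] | None] = [
        _frame_centroid(stack.frames[i], min_area, max_area) for i in range(n)
    ]
    n_empty = sum(c is None for c in centroids)
    if n_empty > n / 2:
        raise ValueError(
            f"tracking failed: {n_empty}/{n} frames contain no valid object"
        )

    # split into contiguous runs: a run breaks on a gap > max_gap or a jump
    # > max_step between consecutive detections
    runs: list[list[tuple[int, float, float]]] = []
    current: list[tuple[int, float, float]] = []
    last_seen: tuple[int, float, float] | None = None
    for i, c in enumerate(centroids):
        if c is None:
            continue
        cx, cy = c
        if last_seen is not None:
            gap = i - last_seen[0] - 1
            step = np.hypot(cx - last_seen[1], cy - last_seen[2])
            if gap > max_gap or step > max_step:
                runs.append(current)
                current = []
        current.append((i, cx, cy))
        last_seen = (i, cx, cy)
    if current:
        runs.append(current)
    if not runs or max(len(r) for r in runs) == 0:
        raise ValueError("tracking failed: no contiguous track found")
    best = max(runs, key=len)

    # bridge interior gaps (<= max_gap by construction) by interpolation
    frames_out: list[int] = []
    xs: list[float] = []
    ys: list[float] = []
    for j, (i, cx, cy) in enumerate(best):
        if j > 0:
            prev_i, prev_x, prev_y = best[j - 1]
            for k in range(prev_i + 1, i):
                w = (k - prev_i) / (i - prev_i)
                frames_out.append(k)
                xs.append(prev_x + w * (cx - prev_x))
                ys.append(prev_y + w * (cy - prev_y))
        frames_out.append(i)
        xs.append(cx)
        ys.append(cy)
    return Trajectory(frames_out, xs, ys, frame_rate=stack.frame_rate)


def preprocess_pair(
    experiment: FrameStack,
    background: FrameStack,
    bin_factor: int = 2,
    antialias_iterations: int = 1,
    min_area: float = 50.0,
    max_area: float = 5000.0,
    max_step: float = 50.0,
) -> Trajectory:
    """Run the full pipeline: bin, align, subtract, threshold, open, track."""
    experiment = spatial_bin(experiment, bin_factor)
    background = spatial_bin(background, bin_factor)
    aligned = align_background(experiment, background)
    diff = subtract_background(experiment, aligned)
    binary = threshold_minimum(diff)
    cleaned = antialias(binary, antialias_iterations)
    return track_blobs(cleaned, min_area, max_area, max_step)
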