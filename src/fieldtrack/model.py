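"""Domain types shared by every analysis stage.

The central currency is the :class:`Trajectory`: a time-ordered sequence of
animal centroid positions in image coordinates (origin top-left, ``x`` =
column, ``y`` = row, ``y`` increasing downward), together with the frame rate
and the spatial scale (millimetres per pixel) needed to report physical
units.  All computation happens in raw pixels; millimetres appear only at
reporting time via ``scale``.

Frame indices are 0-based throughout the library; the 1-based convention of
tracker result files on disk is confined to the parser in
:mod:`fieldtrack.io_formats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "TrackPoint",
    "Trajectory",
    "ArenaGeometry",
    "ROISpec",
    "AnalysisConfig",
    "KinematicsResult",
    "LateralityResult",
    "ROIResult",
    "validate_config",
]


@dataclass(frozen=True)
class TrackPoint:
    """One centroid sample: frame index, time in seconds, position in pixels."""

    frame_index: int
    t: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError("x, y must be finite")
        if self.x < 0 or self.y < 0:
            raise ValueError("x, y must be non-negative")


class Trajectory:
    """Time-ordered centroid track of a single animal.

    Parameters
    ----------
    frames : array-like of int
        Strictly increasing 0-based frame indices.
    x, y : array-like of float
        Centroid coordinates in pixels (image convention, y down).
    frame_rate : float
        Acquisition rate in frames per second.
    scale : float
        Spatial scale in millimetres per pixel.
    source_id : str
        Free-text label identifying the recording.
    """

    def __init__(
        self,
        frames: Sequence[int],
        x: Sequence[float],
        y: Sequence[float],
        frame_rate: float = 25.0,
        scale: float = 1.0,
        source_id: str = "",
    ) -> None:
        if frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if scale <= 0:
            raise ValueError("scale must be > 0")
        frames = np.asarray(frames, dtype=np.int64)
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if not (frames.shape == x.shape == y.shape) or frames.ndim != 1:
            raise ValueError("frames, x, y must be 1-D arrays of equal length")
        if frames.size and np.any(np.diff(frames) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if frames.size and frames[0] < 0:
            raise ValueError("frame indices must be >= 0")
        if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
            raise ValueError("coordinates must be finite")
        self.frames = frames
        self.x = x
        self.y = y
        self.frame_rate = float(frame_rate)
        self.scale = float(scale)
        self.source_id = source_id

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds (frame index / frame rate)."""
        return self.frames / self.frame_rate

    def __len__(self) -> int:
        return int(self.frames.size)

    def __iter__(self) -> Iterator[TrackPoint]:
        for f, t, x, y in zip(self.frames, self.t, self.x, self.y):
            yield TrackPoint(int(f), float(t), float(x), float(y))

    def __getitem__(self, i: int) -> TrackPoint:
        return TrackPoint(
            int(self.frames[i]), float(self.t[i]), float(self.x[i]), float(self.y[i])
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Trajectory):
            return NotImplemented
        return (
            np.array_equal(self.frames, other.frames)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and self.frame_rate == other.frame_rate
            and self.scale == other.scale
        )

    def __repr__(self) -> str:
        return (
            f"Trajectory(n={len(self)}, frame_rate={self.frame_rate}, "
            f"scale={self.scale}, source_id={self.source_id!r})"
        )

    def with_coords(self, x: np.ndarray, y: np.ndarray) -> "Trajectory":
        """New trajectory with the same timing but replaced coordinates."""
        return Trajectory(
            self.frames.copy(), x, y, self.frame_rate, self.scale, self.source_id
        )

    def select_frames(self, first: int, last: int) -> "Trajectory":
        """Restrict to samples whose frame index lies in ``[first, last]``."""
        keep = (self.frames >= first) & (self.frames <= last)
        return Trajectory(
            self.frames[keep],
            self.x[keep],
            self.y[keep],
            self.frame_rate,
            self.scale,
            self.source_id,
        )


@dataclass(frozen=True)
class ArenaGeometry:
    """Detected circular arena perimeter in pixel coordinates."""

    centre_x: float
    centre_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("arena radius must be > 0")


@dataclass(frozen=True)
class ROISpec:
    """A circular region of interest: label plus centre and radius in pixels."""

    label: str
    centre_x: float
    centre_y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be > 0")


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of one analysis run.

    ``downsample_factor`` defaults to 10 so a 25 fps recording is analysed at
    an effective 2.5 samples/s.  ``stop_epsilon`` is the displacement (pixels)
    at or below which a step counts as stationary; the default 0 demands exact
    coordinate repetition, which occurs naturally on integer-pixel tracker
    output but can be loosened for sub-pixel centroids.
    """

    frame_rate: float = 25.0
    frame_range: tuple[int, int] | str = "all"
    scale: float = 1.0
    downsample_factor: int = 10
    stop_epsilon: float = 0.0
    rois: tuple[ROISpec, ...] = ()
    exclude_stops: bool = False
    curvature_statistic: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        object.__setattr__(self, "rois", tuple(self.rois))

    def replace(self, **kw) -> "AnalysisConfig":
        return replace(self, **kw)


def validate_config(config: AnalysisConfig) -> AnalysisConfig:
    """Check a configuration against its invariants; return it unchanged.

    Raises ``ValueError`` for more than 4 ROIs, non-positive scale or frame
    rate, a downsample factor below 1, a negative stop epsilon, or a malformed
    frame range.
    """
    if config.frame_rate <= 0:
        raise ValueError("frame_rate must be > 0")
    if config.scale <= 0:
        raise ValueError("scale must be > 0")
    if config.downsample_factor < 1:
        raise ValueError("downsample_factor must be >= 1")
    if config.stop_epsilon < 0:
        raise ValueError("stop_epsilon must be >= 0")
    if len(config.rois) > 4:
        raise ValueError("at most 4 ROIs can be measured simultaneously")
    if config.curvature_statistic not in ("mean", "median"):
        raise ValueError("curvature_statistic must be 'mean' or 'median'")
    if config.frame_range != "all":
        first, last = config.frame_range
        if first < 0 or last < first:
            raise ValueError("frame_range must satisfy 0 <= first <= last")
    return config


@dataclass
class KinematicsResult:
    """Per-sample kinematics plus summary statistics.

    ``increments`` are the pixel distances between consecutive retained
    samples; ``speeds`` are instantaneous speeds in mm/s from central
    differences; ``total_distance`` is in millimetres.
    """

    increments: np.ndarray
    speeds: np.ndarray
    stop_flags: np.ndarray
    total_distance: float
    mean_speed: float
    speed_sem: float
    stop_fraction: float
    n_samples: int
    effective_frame_rate: float
    distance_over_time_speed: float  # total distance / elapsed time, mm/s


@dataclass
class LateralityResult:
    """Turning behaviour of one trajectory.

    ``lratio`` is left-step count over right-step count; ``offset`` is
    ``|1 - lratio|`` (0 = no turning bias).  ``curvature_radii`` are per-sample
    osculating-circle radii in millimetres, ``+inf`` on straight segments.
    """

    headings: np.ndarray
    turn_angles: np.ndarray
    labels: list[str]
    n_left: int
    n_right: int
    n_straight: int
    n_backward: int
    lratio: float
    lratio_defined: bool
    offset: float
    curvature_radii: np.ndarray
    mean_curvature_radius: float
    curvature_defined: bool
    infinite_radius_fraction: float


@dataclass
class ROIResult:
    """Fractional occupancy per region of interest, keyed by ROI label."""

    fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for label, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"ROI fraction for {label!r} outside [0, 1]")
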