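"""Path kinematics: downsampling, distance increments, stops, speed.

All measures are computed on the downsampled coordinate series (by default
every 10th sample of a 25 fps track, i.e. an effective 2.5 samples/s).  The
distance increment between consecutive retained samples is the Euclidean
chord

    dd_i = sqrt((x_i - x_{i-1})^2 + (y_i - y_{i-1})^2),

a step with dd_i <= stop_epsilon counts as a stop, and instantaneous speed
comes from 2nd-order central differences of x(t) and y(t):

    v_i = scale * sqrt(x'_i^2 + y'_i^2)   [mm/s].
"""

from __future__ import annotations

import numpy as np

from .model import AnalysisConfig, KinematicsResult, Trajectory, validate_config

__all__ = [
    "downsample",
    "distance_increments",
    "stop_fraction",
    "central_derivatives",
    "instantaneous_speed",
    "summarize_kinematics",
]


def downsample(traj: Trajectory, factor: int) -> Trajectory:
    """Keep every ``factor``-th sample, starting at the first.

    The effective frame rate of the result is ``traj.frame_rate / factor``;
    frame indices are renumbered consecutively so timing stays consistent.
    Raises if fewer than 3 samples remain (central differentiation needs a
    three-sample window).
    """
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return traj
    idx = np.arange(0, len(traj), factor)
    if idx.size < 3:
        raise ValueError(
            f"downsampling by {factor} leaves {idx.size} points; at least 3 required"
        )
    return Trajectory(
        np.arange(idx.size),
        traj.x[idx],
        traj.y[idx],
        frame_rate=traj.frame_rate / factor,
        scale=traj.scale,
        source_id=traj.source_id,
    )


def distance_increments(traj: Trajectory) -> np.ndarray:
    """Euclidean distance (pixels) between each consecutive sample pair."""
    if len(traj) < 2:
        raise ValueError("need at least 2 points for distance increments")
    return np.hypot(np.diff(traj.x), np.diff(traj.y))


def stop_fraction(increments: np.ndarray, n: int, epsilon: float = 0.0) -> float:
    """Fraction of stop samples, normalised over the n trajectory points.

    A time point is a stop when its displacement from the previous sample is
    at most ``epsilon`` pixels (exact equality to zero when ``epsilon`` is 0).
    """
    increments = np.asarray(increments)
    if increments.size == 0:
        raise ValueError("increments must be nonempty")
    return float(np.count_nonzero(increments <= epsilon)) / n


def central_derivatives(
    values: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """2nd-order central differences with replicated end values.

    Interior samples use the three-point stencils

        v'_i  = (v_{i+1} - v_{i-1}) / (2 dt)
        v''_i = (v_{i+1} - 2 v_i + v_{i-1}) / dt^2

    and the series is padded by replicating the first and last value, so the
    endpoints use the same stencils on the padded series.  Exact for
    polynomials of degree <= 2 at interior points.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 3:
        raise ValueError("need at least 3 values for central differentiation")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    padded = np.concatenate(([values[0]], values, [values[-1]]))
    first = (padded[2:] - padded[:-2]) / (2.0 * dt)
    second = (padded[2:] - 2.0 * padded[1:-1] + padded[:-2]) / (dt * dt)
    return first, second


def instantaneous_speed(
    x_dot: np.ndarray, y_dot: np.ndarray, scale: float = 1.0
) -> np.ndarray:
    """Speed magnitude in mm/s from coordinate time-derivatives in px/s."""
    x_dot = np.asarray(x_dot)
    y_dot = np.asarray(y_dot)
    if x_dot.shape != y_dot.shape:
        raise ValueError("x_dot and y_dot must have equal length")
    return scale * np.hypot(x_dot, y_dot)


def _prepare(traj: Trajectory, config: AnalysisConfig) -> Trajectory:
    """Apply frame-range selection then downsampling, per the analysis order."""
    validate_config(config)
    if config.frame_range != "all":
        first, last = config.frame_range
        if first > traj.frames.max(initial=-1):
            raise ValueError("frame_range lies outside the trajectory")
        traj = traj.select_frames(first, last)
    return downsample(traj, config.downsample_factor)


def summarize_kinematics(
    traj: Trajectory, config: AnalysisConfig, *, prepared: bool = False
) -> KinematicsResult:
    """Full kinematics summary of one trajectory.

    Frame-range selection is applied before downsampling.  ``total_distance``
    is the chord-sum in millimetres; ``mean_speed`` and its s.e.m. (sample
    s.d. / sqrt(m)) are over the per-sample instantaneous speeds, including
    stop samples unless ``config.exclude_stops``.  The alternative speed
    estimate total-distance / elapsed-time is reported alongside.
    """
    ds = traj if prepared else _prepare(traj, config)
    n = len(ds)
    if n < 3:
        raise ValueError("need at least 3 downsampled points")
    scale = config.scale
    dt = 1.0 / ds.frame_rate

    increments = distance_increments(ds)
    stops = increments <= config.stop_epsilon
    sfrac = stop_fraction(increments, n, config.stop_epsilon)

    x_dot, _ = central_derivatives(ds.x, dt)
    y_dot, _ = central_derivatives(ds.y, dt)
    speeds = instantaneous_speed(x_dot, y_dot, scale)

    speed_samples = speeds
    if config.exclude_stops:
        # speeds are per sample, stops per step; a sample counts as moving
        # when at least one of its adjacent steps moved
        moving = np.zeros(n, dtype=bool)
        moving[:-1] |= ~stops
        moving[1:] |= ~stops
        speed_samples = speeds[moving]
    m = speed_samples.size
    mean_speed = float(np.mean(speed_samples)) if m else 0.0
    speed_sem = float(np.std(speed_samples, ddof=1) / np.sqrt(m)) if m > 1 else 0.0

    total_distance = scale * float(np.sum(increments))
    elapsed = (n - 1) * dt
    return KinematicsResult(
        increments=increments,
        speeds=speeds,
        stop_flags=stops,
        total_distance=total_distance,
        mean_speed=mean_speed,
        speed_sem=speed_sem,
        stop_fraction=sfrac,
        n_samples=n,
        effective_frame_rate=ds.frame_rate,
        distance_over_time_speed=total_distance / elapsed if elapsed > 0 else 0.0,
    )
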