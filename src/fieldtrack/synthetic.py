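"""Synthetic ground-truth trajectories and rendered arena videos.

Emulates the mechanical calibration rig — a mouse-sized object swept around
the arena on a speed-controlled rotor arm — plus straight-line, stop-and-go
and confined-random-walk motion programs.  Every program carries closed-form
analytic expectations (distance, speed, curvature radius, turn direction,
stop fraction) that are independent of the tracking pipeline, so pipeline
accuracy is always measured against ground truth the pipeline never saw.

For circular motion at angular speed ``omega`` (rad/s, positive =
anticlockwise in world space, i.e. a left turn) sampled at ``frame_rate``,
the expected polyline distance is the chord sum

    (n - 1) * 2 r sin(|omega| dt / 2),

which is what a tracker measuring straight segments between samples can at
best recover — the comparison is chord against chord, as in a physical rotor
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .model import AnalysisConfig, ArenaGeometry, Trajectory
from .preprocess import FrameStack, preprocess_pair
from .kinematics import summarize_kinematics
from .laterality import summarize_laterality

__all__ = [
    "MotionSpec",
    "GroundTruth",
    "generate_trajectory",
    "render_video",
    "calibration_report",
    "default_calibration_specs",
]


@dataclass(frozen=True)
class MotionSpec:
    """A programmed motion with analytically known statistics.

    ``kind`` selects the program: ``circle`` (rotor arm: constant angular
    speed on a circle of ``radius``), ``line`` (constant velocity),
    ``stop_and_go`` (alternating dwell and move blocks) or ``random_walk``
    (seeded correlated walk confined to the arena).  ``angular_speed`` is
    signed: positive is anticlockwise in world space (a left turn), negative
    clockwise.
    """

    kind: Literal["circle", "line", "stop_and_go", "random_walk"]
    centre_x: float = 160.0
    centre_y: float = 120.0
    radius: float = 60.0
    angular_speed: float = 0.1
    linear_speed: float = 5.0
    heading: float = 0.0
    duration: float = 100.0
    frame_rate: float = 25.0
    dwell_fraction: float = 0.4
    block_length: int = 10
    arena_radius: float = 110.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if self.kind == "circle" and self.radius <= 0:
            raise ValueError("circle requires radius > 0")
        if self.kind not in ("circle", "line", "stop_and_go", "random_walk"):
            raise ValueError(f"unknown motion kind {self.kind!r}")


@dataclass(frozen=True)
class GroundTruth:
    """Closed-form expectations for a MotionSpec, in pixels and seconds."""

    expected_total_distance: float
    expected_speed: float
    expected_curvature_radius: float
    expected_turn_direction: Literal["left", "right", "straight"]
    expected_stop_fraction: float


def generate_trajectory(spec: MotionSpec) -> tuple[Trajectory, GroundTruth]:
    """Sample a motion program and return it with its analytic expectations.

    Coordinates are image-convention (y down), so an anticlockwise world
    motion has y = cy - r sin(omega t).
    """
    n = int(round(spec.duration * spec.frame_rate)) + 1
    if n < 3:
        raise ValueError("spec yields fewer than 3 samples")
    dt = 1.0 / spec.frame_rate
    t = np.arange(n) * dt

    if spec.kind == "circle":
        phase = spec.angular_speed * t
        x = spec.centre_x + spec.radius * np.cos(phase)
        y = spec.centre_y - spec.radius * np.sin(phase)
        chord = 2.0 * spec.radius * math.sin(abs(spec.angular_speed) * dt / 2.0)
        truth = GroundTruth(
            expected_total_distance=(n - 1) * chord,
            expected_speed=abs(spec.angular_speed) * spec.radius,
            expected_curvature_radius=spec.radius,
            expected_turn_direction="left" if spec.angular_speed > 0 else "right",
            expected_stop_fraction=0.0,
        )
    elif spec.kind == "line":
        x = spec.centre_x + spec.linear_speed * t * math.cos(spec.heading)
        y = spec.centre_y - spec.linear_speed * t * math.sin(spec.heading)
        truth = GroundTruth(
            expected_total_distance=(n - 1) * spec.linear_speed * dt,
            expected_speed=spec.linear_speed,
            expected_curvature_radius=float("inf"),
            expected_turn_direction="straight",
            expected_stop_fraction=0.0,
        )
    elif spec.kind == "stop_and_go":
        x, y, stop_frac = _stop_and_go(spec, n, dt)
        truth = GroundTruth(
            expected_total_distance=float(
                np.sum(np.hypot(np.diff(x), np.diff(y)))
            ),
            expected_speed=spec.linear_speed,
            expected_curvature_radius=float("inf"),
            expected_turn_direction="straight",
            expected_stop_fraction=stop_frac,
        )
    else:  # random_walk
        x, y = _random_walk(spec, n, dt)
        truth = GroundTruth(
            expected_total_distance=float(
                np.sum(np.hypot(np.diff(x), np.diff(y)))
            ),
            expected_speed=spec.linear_speed,
            expected_curvature_radius=float("nan"),
            expected_turn_direction="straight",
            expected_stop_fraction=0.0,
        )

    traj = Trajectory(
        np.arange(n), x, y, frame_rate=spec.frame_rate,
        source_id=f"synthetic-{spec.kind}",
    )
    return traj, truth


def _stop_and_go(spec: MotionSpec, n: int, dt: float) -> tuple[np.ndarray, np.ndarray, float]:
    """Alternating dwell/move blocks along +x with exact stop fraction.

    Each cycle of ``block_length`` steps starts with
    ``round(dwell_fraction * block_length)`` zero-displacement steps followed
    by constant-speed steps.  The realised stop fraction (stop steps over n
    samples) is returned exactly.
    """
    dwell_per_block = int(round(spec.dwell_fraction * spec.block_length))
    step = spec.linear_speed * dt
    x = np.empty(n)
    y = np.full(n, spec.centre_y)
    x[0] = spec.centre_x
    stops = 0
    for i in range(1, n):
        in_block = (i - 1) % spec.block_length
        if in_block < dwell_per_block:
            x[i] = x[i - 1]
            stops += 1
        else:
            x[i] = x[i - 1] + step
    return x, y, stops / n


def _random_walk(spec: MotionSpec, n: int, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Seeded heading-correlated walk at constant speed, confined to the arena.

    The heading performs a wrapped Gaussian walk (s.d. 0.5 rad per step); a
    step that would leave 90% of the arena radius is deflected back toward
    the centre.
    """
    rng = np.random.default_rng(spec.seed)
    x = np.empty(n)
    y = np.empty(n)
    x[0], y[0] = spec.centre_x, spec.centre_y
    heading = rng.uniform(0, 2 * np.pi)
    step = spec.linear_speed * dt
    limit = 0.9 * spec.arena_radius
    for i in range(1, n):
        heading += rng.normal(0.0, 0.5)
        nx = x[i - 1] + step * math.cos(heading)
        ny = y[i - 1] - step * math.sin(heading)
        if (nx - spec.centre_x) ** 2 + (ny - spec.centre_y) ** 2 > limit**2:
            # head back toward the arena centre (world-convention heading)
            heading = math.atan2(y[i - 1] - spec.centre_y,
                                 spec.centre_x - x[i - 1])
            nx = x[i - 1] + step * math.cos(heading)
            ny = y[i - 1] - step * math.sin(heading)
        x[i], y[i] = nx, ny
    return x, y


def render_video(
    traj: Trajectory,
    arena: ArenaGeometry,
    blob_radius: float = 8.0,
    noise_sd: float = 0.0,
    width: int = 320,
    height: int = 240,
    seed: int = 0,
    floor_intensity: int = 200,
    surround_intensity: int = 30,
    blob_intensity: int = 60,
) -> tuple[FrameStack, FrameStack]:
    """Render an (experiment, background) video pair for a trajectory.

    The background is a bright arena disc on a dark surround, optionally with
    seeded Gaussian noise; the experiment adds a dark disc of ``blob_radius``
    centred on each trajectory sample.  With ``noise_sd`` 0 renders are
    pixel-exact deterministic; with noise, identical seeds give identical
    stacks.  Raises if any blob would leave the frame.
    """
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    r = blob_radius
    if (
        (traj.x - r).min() < 0
        or (traj.y - r).min() < 0
        or (traj.x + r).max() > width - 1
        or (traj.y + r).max() > height - 1
    ):
        raise ValueError("trajectory (plus blob radius) exits the frame")

    yy, xx = np.ogrid[:height, :width]
    arena_mask = (xx - arena.centre_x) ** 2 + (yy - arena.centre_y) ** 2 <= arena.radius**2
    bg_clean = np.where(arena_mask, floor_intensity, surround_intensity).astype(np.float64)

    rng = np.random.default_rng(seed)
    n = len(traj)
    n_bg = min(n, 250)  # ~10 s of background at 25 fps

    def noisy(base: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return base.astype(np.uint8)
        return np.clip(base + rng.normal(0, noise_sd, base.shape), 0, 255).astype(np.uint8)

    background = np.stack([noisy(bg_clean) for _ in range(n_bg)])

    experiment = np.empty((n, height, width), dtype=np.uint8)
    pad = int(math.ceil(r)) + 1
    for i in range(n):
        frame = bg_clean.copy()
        cx, cy = traj.x[i], traj.y[i]
        x0, x1 = max(int(cx) - pad, 0), min(int(cx) + pad + 1, width)
        y0, y1 = max(int(cy) - pad, 0), min(int(cy) + pad + 1, height)
        sub_yy, sub_xx = np.ogrid[y0:y1, x0:x1]
        blob = (sub_xx - cx) ** 2 + (sub_yy - cy) ** 2 <= r**2
        patch = frame[y0:y1, x0:x1]
        patch[blob] = blob_intensity
        experiment[i] = noisy(frame)

    fr = traj.frame_rate
    return FrameStack(experiment, fr), FrameStack(background, fr)


def default_calibration_specs(
    arena_radius: float = 110.0,
    angular_speed: float = 0.5,
    duration: float = 800.0,
    frame_rate: float = 2.5,
    include_clockwise: bool = True,
) -> list[MotionSpec]:
    """The standard rotor-style calibration suite.

    Three arm positions — circle radii at 0.27, 0.55 and 0.8 of the arena
    radius — at one constant angular speed, mirroring a rotor rig whose arm
    carries the object at three different radii.  With ``include_clockwise``
    the middle radius is repeated with reversed rotation so both turn signs
    are exercised.
    """
    radii = [0.27 * arena_radius, 0.55 * arena_radius, 0.80 * arena_radius]
    specs = [
        MotionSpec(
            kind="circle",
            radius=rr,
            angular_speed=angular_speed,
            duration=duration,
            frame_rate=frame_rate,
            arena_radius=arena_radius,
        )
        for rr in radii
    ]
    if include_clockwise:
        specs.append(
            MotionSpec(
                kind="circle",
                radius=radii[1],
                angular_speed=-angular_speed,
                duration=duration,
                frame_rate=frame_rate,
                arena_radius=arena_radius,
            )
        )
    return specs


@dataclass
class CalibrationRow:
    """One (spec, parameter) line of a calibration report."""

    spec_label: str
    parameter: str
    observed: float
    expected: float
    percent_accuracy: float


def percent_accuracy(observed: float, expected: float) -> float:
    """100 * (1 - |observed - expected| / expected)."""
    return 100.0 * (1.0 - abs(observed - expected) / expected)


def calibration_report(
    specs: list[MotionSpec],
    blob_radius: float = 8.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    width: int = 320,
    height: int = 240,
    bin_factor: int = 1,
) -> tuple[list[CalibrationRow], list[tuple[str, str]]]:
    """Run the full pipeline on each spec and report accuracy per parameter.

    Each spec is rendered to an (experiment, background) video pair, run
    through the complete preprocessing/tracking/analysis chain, and the
    recovered total distance, mean speed and curvature radius are compared
    against the spec's closed-form ground truth.  Returns the report rows
    and a list of (spec_label, message) failures; a failing spec never
    aborts the remaining specs.
    """
    if not specs:
        raise ValueError("at least one MotionSpec required")
    rows: list[CalibrationRow] = []
    failures: list[tuple[str, str]] = []
    for k, spec in enumerate(specs):
        label = f"{spec.kind}#{k}(r={spec.radius:g},w={spec.angular_speed:g})"
        try:
            traj, truth = generate_trajectory(spec)
            arena_k = ArenaGeometry(spec.centre_x, spec.centre_y, spec.arena_radius)
            exp, bg = render_video(
                traj, arena_k, blob_radius=blob_radius, noise_sd=noise_sd,
                width=width, height=height, seed=seed + k,
            )
            tracked = preprocess_pair(exp, bg, bin_factor=bin_factor)
            # rendered at the effective analysis rate: no further downsampling
            config = AnalysisConfig(
                frame_rate=tracked.frame_rate, downsample_factor=1, scale=1.0
            )
            kin = summarize_kinematics(tracked, config)
            lat = summarize_laterality(tracked, config)
            observed = {
                "total_distance": kin.total_distance,
                "mean_speed": kin.mean_speed,
                "curvature_radius": lat.mean_curvature_radius,
            }
            expected = {
                "total_distance": truth.expected_total_distance / bin_factor,
                "mean_speed": truth.expected_speed / bin_factor,
                "curvature_radius": truth.expected_curvature_radius / bin_factor,
            }
            for param in observed:
                rows.append(
                    CalibrationRow(
                        spec_label=label,
                        parameter=param,
                        observed=observed[param],
                        expected=expected[param],
                        percent_accuracy=percent_accuracy(
                            observed[param], expected[param]
                        ),
                    )
                )
        except Exception as exc:  # report and continue with remaining specs
            failures.append((label, str(exc)))
    return rows, failures
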