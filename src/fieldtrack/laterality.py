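"""Turning laterality and path curvature.

Heading at step i is the angle of the displacement vector from sample i to
i+1.  Because image coordinates put y downward, the y component is negated
before ``atan2`` so that a positive turn angle means an anticlockwise heading
change in world space — the animal turning left.  Within each sliding window
of three samples the step across samples 2-3 is expressed relative to the
step across samples 1-2:

    dtheta_i = wrap(theta_i - theta_{i-1})   in (-pi, pi]

and the step is classified as forward-left (0 < dtheta < pi/2), forward-right
(-pi/2 < dtheta < 0), forward-straight (dtheta = 0) or backward
(|dtheta| >= pi/2).  LRatio is the left over right step count and
|1 - LRatio| the laterality offset.  The curvature radius is that of the
osculating ("inner tangential") circle,

    R = (x'^2 + y'^2)^{3/2} / |x' y'' - y' x''|,

from the same central differences as the speed, infinite on straight
segments.
"""

from __future__ import annotations

import numpy as np

from .kinematics import _prepare, central_derivatives
from .model import AnalysisConfig, LateralityResult, Trajectory

__all__ = [
    "heading_angles",
    "turn_angles",
    "classify_direction",
    "lratio_and_offset",
    "curvature_radius",
    "summarize_laterality",
]

_CURVATURE_DENOM_FLOOR = 1e-9


def heading_angles(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-step heading angles in radians, plus a stationary-step mask.

    A zero-length step has no defined heading; the previous heading is
    carried forward (0 if the track starts stationary) and the step is
    flagged stationary so it can be excluded from turn classification.
    """
    if len(traj) < 2:
        raise ValueError("need at least 2 points for headings")
    dx = np.diff(traj.x)
    dy = np.diff(traj.y)
    stationary = (dx == 0) & (dy == 0)
    theta = np.arctan2(-dy, dx)  # y negated: image y points down
    prev = 0.0
    for i in range(theta.size):
        if stationary[i]:
            theta[i] = prev
        else:
            prev = theta[i]
    return theta, stationary


def wrap_angle(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap angle(s) into the half-open interval (-pi, pi]."""
    wrapped = -np.remainder(-np.asarray(a, dtype=np.float64) + np.pi, 2 * np.pi) + np.pi
    return wrapped


def turn_angles(headings: np.ndarray) -> np.ndarray:
    """Heading change per sliding window, wrapped into (-pi, pi]."""
    headings = np.asarray(headings)
    if headings.size < 2:
        raise ValueError("need at least 2 headings for turn angles")
    return wrap_angle(np.diff(headings))


def classify_direction(dtheta: float) -> str:
    """Four-way direction label for one turn angle in (-pi, pi].

    Exactly zero is straight; |dtheta| >= pi/2 (including exactly pi/2) is
    backward; otherwise the sign decides left (positive) or right.
    """
    if dtheta == 0.0:
        return "straight"
    if abs(dtheta) >= np.pi / 2:
        return "backward"
    return "left" if dtheta > 0 else "right"


def lratio_and_offset(labels: list[str]) -> tuple[float, float, bool]:
    """LRatio (left/right step count) and laterality offset |1 - LRatio|.

    With no right-labelled step the ratio is undefined: returns
    ``(inf, inf, False)`` rather than raising.
    """
    n_left = labels.count("left")
    n_right = labels.count("right")
    if n_right == 0:
        return float("inf"), float("inf"), False
    lratio = n_left / n_right
    return lratio, abs(1.0 - lratio), True


def curvature_radius(
    x_dot: np.ndarray,
    x_ddot: np.ndarray,
    y_dot: np.ndarray,
    y_ddot: np.ndarray,
    scale: float = 1.0,
) -> np.ndarray:
    """Osculating-circle radius (mm) at each sample; +inf when straight."""
    arrs = [np.asarray(a, dtype=np.float64) for a in (x_dot, x_ddot, y_dot, y_ddot)]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("derivative lists must have equal length")
    x_dot, x_ddot, y_dot, y_ddot = arrs
    denom = np.abs(x_dot * y_ddot - y_dot * x_ddot)
    speed_sq = x_dot**2 + y_dot**2
    with np.errstate(divide="ignore", invalid="ignore"):
        radii = np.where(
            denom < _CURVATURE_DENOM_FLOOR,
            np.inf,
            scale * speed_sq**1.5 / denom,
        )
    return radii


def summarize_laterality(
    traj: Trajectory, config: AnalysisConfig, *, prepared: bool = False
) -> LateralityResult:
    """Full laterality summary on the downsampled trajectory.

    Stationary (zero-length) steps are excluded from the classification
    counts and from the LRatio.  The curvature statistic is the mean (or
    median, per config) over finite radii only; the infinite-radius fraction
    is reported separately.  A trajectory with no finite radius reports NaN
    with ``curvature_defined=False``.
    """
    ds = traj if prepared else _prepare(traj, config)
    if len(ds) < 3:
        raise ValueError("need at least 3 downsampled points")
    dt = 1.0 / ds.frame_rate

    headings, stationary = heading_angles(ds)
    dthetas = turn_angles(headings)
    # window i covers steps i and i+1; classify only fully moving windows
    moving_window = ~(stationary[:-1] | stationary[1:])
    labels = [
        classify_direction(float(d)) for d, m in zip(dthetas, moving_window) if m
    ]
    lratio, offset, defined = lratio_and_offset(labels)

    x_dot, x_ddot = central_derivatives(ds.x, dt)
    y_dot, y_ddot = central_derivatives(ds.y, dt)
    radii = curvature_radius(x_dot, x_ddot, y_dot, y_ddot, config.scale)
    finite = np.isfinite(radii)
    if finite.any():
        stat = np.median if config.curvature_statistic == "median" else np.mean
        mean_radius = float(stat(radii[finite]))
        curvature_defined = True
    else:
        mean_radius = float("nan")
        curvature_defined = False

    return LateralityResult(
        headings=headings,
        turn_angles=dthetas,
        labels=labels,
        n_left=labels.count("left"),
        n_right=labels.count("right"),
        n_straight=labels.count("straight"),
        n_backward=labels.count("backward"),
        lratio=lratio,
        lratio_defined=defined,
        offset=offset,
        curvature_radii=radii,
        mean_curvature_radius=mean_radius,
        curvature_defined=curvature_defined,
        infinite_radius_fraction=float(np.mean(~finite)),
    )
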