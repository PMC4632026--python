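"""fieldtrack: open-field rodent trajectory tracking and kinematics.

Segments and tracks a single animal in overhead arena video via background
subtraction, then quantifies its movement: distance travelled, instantaneous
speed, stop-time fraction, turning laterality (left/right counts, LRatio,
laterality offset), path curvature radius and circular region-of-interest
occupancy.  A synthetic rotor-style calibration suite validates the full
pipeline against closed-form ground truth.
"""

from __future__ import annotations

from .model import (
    AnalysisConfig,
    ArenaGeometry,
    KinematicsResult,
    LateralityResult,
    ROIResult,
    ROISpec,
    TrackPoint,
    Trajectory,
    validate_config,
)
from .kinematics import (
    central_derivatives,
    distance_increments,
    downsample,
    instantaneous_speed,
    stop_fraction,
    summarize_kinematics,
)
from .kinematics import _prepare as _prepare_trajectory
from .laterality import (
    classify_direction,
    curvature_radius,
    heading_angles,
    lratio_and_offset,
    summarize_laterality,
    turn_angles,
)
from .roi import novelty_preference, roi_fractions
from .preprocess import (
    BinaryStack,
    FrameStack,
    antialias,
    align_background,
    detect_arena,
    preprocess_pair,
    spatial_bin,
    subtract_background,
    threshold_minimum,
    track_blobs,
)
from .synthetic import (
    GroundTruth,
    MotionSpec,
    calibration_report,
    default_calibration_specs,
    generate_trajectory,
    render_video,
)

__version__ = "0.1.0"


def analyze_trajectory(
    traj: Trajectory, config: AnalysisConfig
) -> tuple[KinematicsResult, LateralityResult, ROIResult | None]:
    """Run the complete analysis of one trajectory under one configuration.

    Applies frame-range selection then downsampling once, and computes the
    kinematics, laterality and (when ROIs are configured) ROI occupancy on
    the same prepared series.
    """
    validate_config(config)
    prepared = _prepare_trajectory(traj, config)
    kin = summarize_kinematics(prepared, config, prepared=True)
    lat = summarize_laterality(prepared, config, prepared=True)
    roi = roi_fractions(prepared, config.rois) if config.rois else None
    return kin, lat, roi
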