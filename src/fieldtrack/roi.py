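"""Circular region-of-interest occupancy.

The ROI fraction is the fraction of trajectory samples falling inside a
circular region (closed disc: boundary points count as inside).  Up to four
ROIs may be measured simultaneously; overlapping ROIs are allowed and a
sample may count toward several.  Membership is tested on the same
downsampled trajectory as all other statistics.
"""

from __future__ import annotations

from typing import Sequence

from .model import ROIResult, ROISpec, Trajectory

__all__ = ["roi_fractions", "novelty_preference"]


def roi_fractions(traj: Trajectory, rois: Sequence[ROISpec]) -> ROIResult:
    """Fraction of samples inside each ROI, keyed by ROI label."""
    if not 1 <= len(rois) <= 4:
        raise ValueError("between 1 and 4 ROIs required")
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    fractions = {}
    for roi in rois:
        inside = (traj.x - roi.centre_x) ** 2 + (traj.y - roi.centre_y) ** 2 <= roi.radius**2
        fractions[roi.label] = float(inside.mean())
    return ROIResult(fractions=fractions)


def novelty_preference(
    fractions: ROIResult, object1_label: str, object2_label: str
) -> float:
    """Relative exploration of object 2 versus object 1.

    The ratio of the two occupancy fractions; > 1 indicates preference for
    object 2 (the novel object in a recognition test).  Raises when object 1
    was never visited, since the ratio is then undefined.
    """
    f1 = fractions.fractions[object1_label]
    f2 = fractions.fractions[object2_label]
    if f1 == 0:
        raise ValueError(
            f"novelty preference undefined: zero occupancy for {object1_label!r}"
        )
    return f2 / f1
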