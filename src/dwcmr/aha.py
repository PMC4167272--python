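"""16-segment AHA model for 3-slice short-axis stacks.

Basal and mid slices are divided into six 60-degree sectors (segments 1-6
and 7-12), the apical slice into four 90-degree sectors (13-16), counted
counter-clockwise from the anterior reference ray (the anterior RV
insertion).  The apex-cap 17th segment is not acquired in a 3-slice
short-axis protocol.  Scores are binary per segment; a segment is positive
for infarct when *any* of its voxels meets the classifier criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack

__all__ = [
    "LEVELS",
    "SEGMENT_NAMES",
    "SegmentScore",
    "assign_segments",
    "assign_segments_stack",
    "score_segments",
    "segment_for_angles",
]

LEVELS = ("basal", "mid", "apical")

SEGMENT_NAMES = (
    "basal anterior", "basal anteroseptal", "basal inferoseptal",
    "basal inferior", "basal inferolateral", "basal anterolateral",
    "mid anterior", "mid anteroseptal", "mid inferoseptal",
    "mid inferior", "mid inferolateral", "mid anterolateral",
    "apical anterior", "apical septal", "apical inferior", "apical lateral",
)

_LEVEL_OFFSET = {"basal": 1, "mid": 7, "apical": 13}
_LEVEL_SECTORS = {"basal": 6, "mid": 6, "apical": 4}


@dataclass
class SegmentScore:
    """16 binary values ordered basal 1-6, mid 7-12, apical 13-16."""

    values: np.ndarray
    modality: str = ""
    reviewer: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.shape != (16,):
            raise ValueError("a SegmentScore holds exactly 16 values")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("segment scores are binary")

    @property
    def positive_segments(self) -> np.ndarray:
        """1-based segment numbers scored positive."""
        return np.nonzero(self.values)[0] + 1


def segment_for_angles(level: str, theta_deg) -> np.ndarray:
    """Global AHA segment numbers for angles (deg, CCW from the reference ray)."""
    if level not in _LEVEL_SECTORS:
        raise ValueError(f"unknown slice level {level!r}")
    sectors = _LEVEL_SECTORS[level]
    theta = np.mod(np.asarray(theta_deg, dtype=float), 360.0)
    idx = np.minimum((theta / (360.0 / sectors)).astype(int), sectors - 1)
    return _LEVEL_OFFSET[level] + idx


def assign_segments(
    level: str,
    myocardium: np.ndarray,
    reference: ImageStack,
    reference_angle_deg: float,
) -> np.ndarray:
    """Label one slice's myocardium voxels with global AHA segment numbers.

    Returns a 2-D integer map, 0 outside the myocardium.
    """
    if reference_angle_deg is None:
        raise ValueError("the anterior reference angle is required")
    myocardium = np.asarray(myocardium, dtype=bool)
    if not myocardium.any():
        raise ValueError("myocardium mask is empty")
    _, theta = reference.polar_grid(reference_angle_deg)
    labels = segment_for_angles(level, theta)
    return np.where(myocardium, labels, 0)


def assign_segments_stack(
    myocardium: np.ndarray,
    reference: ImageStack,
    reference_angle_deg: float,
    levels=LEVELS,
) -> np.ndarray:
    """Label a base/mid/apex stack (slice i gets ``levels[i]``)."""
    myocardium = np.asarray(myocardium, dtype=bool)
    if myocardium.shape[0] != len(levels):
        raise ValueError("one slice level per slice is required")
    return np.stack(
        [
            assign_segments(levels[s], myocardium[s], reference, reference_angle_deg)
            for s in range(myocardium.shape[0])
        ]
    )


def score_segments(mask, labels: np.ndarray, modality: str = "", reviewer: str = "") -> SegmentScore:
    """Any-voxel rule: a segment is positive iff >= 1 masked voxel carries its label."""
    m = mask.mask if hasattr(mask, "mask") else np.asarray(mask, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    if labels.shape != m.shape:
        raise ValueError("label map and mask shapes differ")
    if np.any(m & (labels == 0)):
        raise ValueError("labels must cover every masked voxel")
    values = np.zeros(16, dtype=int)
    hit = np.unique(labels[m])
    values[hit[hit > 0] - 1] = 1
    return SegmentScore(values, modality=modality, reviewer=reviewer)
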