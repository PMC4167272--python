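"""Chord-based regional wall motion from cine contours.

For each slice, 100 evenly spaced chords (radial rays from a fixed LV
centre, the reference-phase endocardial centroid) are intersected with the
endo- and epicardial contours.  Regional wall motion per chord is the
maximal excursion of the endocardial intersection point along the chord
across the cardiac cycle, relative to the reference phase (end-diastole).
A fixed centre is used rather than a per-phase centre so that radial
motion is not cancelled by centroid drift.

Akinesis is scored per AHA segment: a segment is akinetic when its mean
absolute chord displacement is <= 3 mm.  The mean (rather than any-chord)
aggregation is a documented choice for noise robustness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aha import SegmentScore
from .core import CineStudy

__all__ = [
    "ChordDisplacementMap",
    "chord_displacement",
    "classify_akinetic",
    "compute_chords",
]


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = cross.sum() / 2.0
    if abs(area) < 1e-12:
        return pts.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * area)
    cy = ((y + yn) * cross).sum() / (6.0 * area)
    return np.array([cx, cy])


def _radius_about(points: np.ndarray, center: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Radial distance of a star-shaped contour along given ray angles."""
    pts = np.asarray(points, dtype=float) - center
    theta = np.mod(np.degrees(np.arctan2(pts[:, 1], pts[:, 0])), 360.0)
    order = np.argsort(theta)
    t = theta[order]
    r = np.hypot(pts[order, 0], pts[order, 1])
    return np.interp(angles_deg, np.concatenate([t, t[:1] + 360.0]),
                     np.concatenate([r, r[:1]]), period=360.0)


@dataclass
class ChordSet:
    """Rays from the LV centre with their endo/epi intersection radii (mm)."""

    center: np.ndarray
    angles_deg: np.ndarray
    endo_radius: np.ndarray
    epi_radius: np.ndarray

    @property
    def lengths(self) -> np.ndarray:
        return self.epi_radius - self.endo_radius


def compute_chords(endo: np.ndarray, epi: np.ndarray, n: int = 100, center=None) -> ChordSet:
    """Define ``n`` evenly spaced chords across the wall.

    Rays leave the LV centre of mass (endocardial centroid unless a centre
    is given) at uniform angular spacing; each must cross the endocardium
    strictly inside the epicardium, otherwise the contours cross and an
    error is raised.
    """
    endo = np.asarray(endo, dtype=float)
    epi = np.asarray(epi, dtype=float)
    c = _polygon_centroid(endo) if center is None else np.asarray(center, dtype=float)
    angles = np.arange(n) * (360.0 / n)
    r_endo = _radius_about(endo, c, angles)
    r_epi = _radius_about(epi, c, angles)
    if np.any(r_endo >= r_epi):
        raise ValueError("contours cross: endocardium is not inside the epicardium")
    return ChordSet(center=c, angles_deg=angles, endo_radius=r_endo, epi_radius=r_epi)


@dataclass
class ChordDisplacementMap:
    """Per-slice chord angles and wall displacement values (mm)."""

    angles_deg: np.ndarray          # (n_chords,)
    displacement: np.ndarray        # (n_slices, n_chords)
    reference_phase: int
    centers: np.ndarray             # (n_slices, 2) fixed LV centres, mm
    segment_labels: np.ndarray | None = None  # (n_slices, n_chords) AHA numbers
    meta: dict = field(default_factory=dict)


def chord_displacement(cine: CineStudy, reference_phase: int = 0, n: int = 100) -> ChordDisplacementMap:
    """Maximal endocardial excursion along each chord across the cycle.

    The chord geometry (centre and angles) is fixed at the reference phase;
    for every other phase the endocardial intersection radius along each ray
    is measured and the largest absolute change from the reference is the
    chord's displacement.
    """
    n_slices = cine.n_slices
    disp = np.zeros((n_slices, n))
    centers = np.zeros((n_slices, 2))
    angles = np.arange(n) * (360.0 / n)
    for s in range(n_slices):
        ref = cine.contours[reference_phase][s]
        if ref is None or "endo" not in ref:
            raise ValueError(f"missing contour for phase {reference_phase}, slice {s}")
        chords = compute_chords(ref["endo"], ref["epi"], n=n)
        centers[s] = chords.center
        excursion = np.zeros(n)
        for p in range(cine.n_phases):
            c = cine.contours[p][s]
            if c is None or "endo" not in c:
                raise ValueError(f"missing contour for phase {p}, slice {s}")
            r_p = _radius_about(np.asarray(c["endo"]), chords.center, angles)
            excursion = np.maximum(excursion, np.abs(r_p - chords.endo_radius))
        disp[s] = excursion
    return ChordDisplacementMap(
        angles_deg=angles,
        displacement=disp,
        reference_phase=reference_phase,
        centers=centers,
    )


def classify_akinetic(
    rwm: ChordDisplacementMap,
    segment_labels: np.ndarray | None = None,
    cutoff_mm: float = 3.0,
) -> SegmentScore:
    """Segments with mean absolute chord displacement <= ``cutoff_mm`` are akinetic.

    ``segment_labels`` assigns every chord a global AHA segment number
    (shape matching ``rwm.displacement``); segments with no chords score 0.
    """
    labels = segment_labels if segment_labels is not None else rwm.segment_labels
    if labels is None:
        raise ValueError("chord segment labels are required")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != rwm.displacement.shape:
        raise ValueError("segment label shape must match the displacement map")
    if np.any(labels <= 0) or np.any(labels > 16):
        raise ValueError("every chord must carry an AHA segment label in 1..16")
    values = np.zeros(16, dtype=int)
    for seg in np.unique(labels):
        mean_disp = np.abs(rwm.displacement[labels == seg]).mean()
        values[seg - 1] = 1 if mean_disp <= cutoff_mm else 0
    return SegmentScore(values, modality="RWM")
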