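"""Semi-automatic infarct classification, sizing and transmurality.

Two standard classifiers, applied identically to ADC maps and
(co-registered) LGE images — only the input image differs:

* n-SD threshold: infarct = myocardial voxels above the mean of a manually
  chosen remote ROI plus ``n`` (default 6) standard deviations.
* FWHM region growing, two stages: (1) grow a connected "seed region" from
  a manually placed seed voxel over voxels >= 50% of the seed intensity;
  (2) keep myocardial voxels >= 50% of that region's maximum, restricted to
  connected components that touch the seed region.

Connectivity is 4-neighbour in-plane with no through-plane growth (slices
are 6 mm apart); multi-slice infarcts are segmented with one seed per
slice.  Infarct volume is reported as a percentage of the myocardial
volume of the three acquired slices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import ImageStack, angle_difference

__all__ = [
    "InfarctMask",
    "fwhm_classify",
    "infarct_volume_pct",
    "threshold_classify",
    "transmurality",
]

_STRUCTURE_2D = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class InfarctMask:
    """Binary infarct classification restricted to the myocardium."""

    mask: np.ndarray
    method: str                      # "threshold" | "fwhm"
    myocardium: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.myocardium = np.asarray(self.myocardium, dtype=bool)
        if self.mask.shape != self.myocardium.shape:
            raise ValueError("mask and myocardium shapes differ")
        if np.any(self.mask & ~self.myocardium):
            raise ValueError("infarct mask must be a subset of the myocardium")
        if not self.provenance:
            raise ValueError("an InfarctMask requires provenance (ROI or seed)")


def _image_data(image) -> np.ndarray:
    if isinstance(image, ImageStack):
        return image.data
    if hasattr(image, "data"):  # ADCMap
        return np.asarray(image.data, dtype=float)
    return np.asarray(image, dtype=float)


def threshold_classify(
    image,
    remote_roi: np.ndarray,
    myocardium: np.ndarray,
    n_sd: float = 6.0,
) -> InfarctMask:
    """Classify voxels above ``mean(remote) + n_sd * SD(remote)``.

    The remote SD uses the sample (ddof=1) convention.  A single-voxel ROI
    has no defined SD and raises; an ROI with zero SD degenerates to a
    cutoff at the remote mean (strictly-greater rule), documented behaviour.
    """
    data = _image_data(image)
    remote_roi = np.asarray(remote_roi, dtype=bool)
    myocardium = np.asarray(myocardium, dtype=bool)
    if not remote_roi.any():
        raise ValueError("remote ROI is empty")
    if np.any(remote_roi & ~myocardium):
        raise ValueError("remote ROI must lie within the myocardium")
    vals = data[remote_roi]
    if vals.size < 2:
        raise ValueError("remote ROI SD undefined for a single voxel")
    cutoff = vals.mean() + n_sd * vals.std(ddof=1)
    mask = myocardium & (data > cutoff)
    return InfarctMask(
        mask,
        "threshold",
        myocardium,
        provenance={"cutoff": float(cutoff), "n_sd": n_sd, "roi_voxels": int(vals.size)},
    )


def _grow_component(candidates: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Connected components (in-plane 4-connectivity) of ``candidates``
    that intersect ``include``, slice by slice."""
    out = np.zeros_like(candidates)
    for s in range(candidates.shape[0]):
        labels, n = ndimage.label(candidates[s], structure=_STRUCTURE_2D)
        if n == 0:
            continue
        hit = np.unique(labels[include[s] & (labels > 0)])
        if hit.size:
            out[s] = np.isin(labels, hit)
    return out


def fwhm_classify(
    image,
    seed_voxel,
    myocardium: np.ndarray,
    fraction: float = 0.5,
) -> InfarctMask:
    """Two-stage full-width-half-maximum classification.

    ``seed_voxel`` is one ``(slice, row, col)`` triple or a sequence of
    them (multi-slice infarcts need one seed per slice — growth never
    crosses slices).  Stage one grows the seed region over connected voxels
    >= ``fraction`` x seed intensity; stage two keeps myocardial voxels >=
    ``fraction`` x max(seed region), restricted to components touching the
    seed region.
    """
    data = _image_data(image)
    myocardium = np.asarray(myocardium, dtype=bool)
    seeds = np.atleast_2d(np.asarray(seed_voxel, dtype=int))
    if seeds.shape[1] != 3:
        raise ValueError("seed voxels must be (slice, row, col) triples")
    seed_mask = np.zeros_like(myocardium)
    for s, r, c in seeds:
        if not myocardium[s, r, c]:
            raise ValueError(f"seed voxel {(s, r, c)} lies outside the myocardium")
        seed_mask[s, r, c] = True

    final = np.zeros_like(myocardium)
    half_maxima = []
    for s, r, c in seeds:
        one_seed = np.zeros_like(myocardium)
        one_seed[s, r, c] = True
        stage1 = myocardium & (data >= fraction * data[s, r, c])
        seed_region = _grow_component(stage1, one_seed)
        region_max = data[seed_region].max()
        half_maxima.append(float(fraction * region_max))
        stage2 = myocardium & (data >= fraction * region_max)
        final |= _grow_component(stage2, seed_region)
    return InfarctMask(
        final,
        "fwhm",
        myocardium,
        provenance={
            "seeds": [tuple(int(v) for v in s) for s in seeds],
            "fraction": fraction,
            "half_maxima": half_maxima,
        },
    )


def infarct_volume_pct(mask, myocardium: np.ndarray | None = None, voxel_volume: float | None = None) -> float:
    """Infarct volume as a percentage of the imaged LV myocardial volume.

    The voxel volume cancels on a common grid; it is accepted for clarity
    when masks come from resampled data.
    """
    if isinstance(mask, InfarctMask):
        m = mask.mask
        myo = mask.myocardium if myocardium is None else np.asarray(myocardium, dtype=bool)
    else:
        m = np.asarray(mask, dtype=bool)
        if myocardium is None:
            raise ValueError("a myocardium mask is required")
        myo = np.asarray(myocardium, dtype=bool)
    if not myo.any():
        raise ValueError("myocardium mask is empty")
    if np.any(m & ~myo):
        raise ValueError("infarct mask must be a subset of the myocardium")
    return 100.0 * float(m.sum()) / float(myo.sum())


def _contour_radius(contour: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    theta = np.mod(np.degrees(np.arctan2(contour[:, 1], contour[:, 0])), 360.0)
    order = np.argsort(theta)
    t = theta[order]
    r = np.hypot(contour[order, 0], contour[order, 1])
    return np.interp(angles_deg, np.concatenate([t, t[:1] + 360.0]),
                     np.concatenate([r, r[:1]]), period=360.0)


def transmurality(
    mask,
    contours: Sequence[dict],
    reference: ImageStack,
    n_rays: int = 360,
    tolerance_px: float = 1.0,
    min_component_voxels: int = 1,
) -> list[bool]:
    """Binary transmurality per connected infarct.

    An infarct is transmural when, along every radial ray interior to its
    angular span, masked voxels cover the wall from endocardium to
    epicardium within a one-voxel tolerance (coverage start/end within
    ``tolerance_px`` pixels; a radial gap of one missing voxel, i.e. about
    two pixel spacings between covered radii, is tolerated).  Rays within
    one voxel's angular width of the span edges are excluded — they are
    discretization artifacts of the wedge boundary.  Components smaller
    than ``min_component_voxels`` (noise specks, not infarcts a reader
    would assess) are skipped.  Returns one flag per 6-connected infarct
    component; an empty mask yields an empty list.
    """
    m = mask.mask if isinstance(mask, InfarctMask) else np.asarray(mask, dtype=bool)
    if len(contours) != reference.n_slices:
        raise ValueError("need one endo/epi contour pair per slice")
    for c in contours:
        if len(c["endo"]) < 3 or len(c["epi"]) < 3:
            raise ValueError("contours must be closed polygons with >= 3 points")
    if not m.any():
        return []
    labels, n = ndimage.label(m)
    r_grid, theta_grid = reference.polar_grid(0.0)
    spacing = reference.spacing
    bin_width = 360.0 / n_rays
    ray_angles = (np.arange(n_rays) + 0.5) * bin_width
    flags = []
    for comp in range(1, n + 1):
        comp_mask = labels == comp
        if comp_mask.sum() < min_component_voxels:
            continue
        transmural = True
        for s in range(reference.n_slices):
            sl = comp_mask[s]
            if not sl.any():
                continue
            endo_r = _contour_radius(np.asarray(contours[s]["endo"]), ray_angles)
            epi_r = _contour_radius(np.asarray(contours[s]["epi"]), ray_angles)
            vox_theta = theta_grid[sl]
            vox_r = r_grid[sl]
            # a voxel covers an arc: half-width of its angular footprint
            half_width = np.degrees(0.75 * spacing / np.maximum(vox_r, spacing))
            diff = np.abs((vox_theta[:, None] - ray_angles[None, :] + 180.0) % 360.0 - 180.0)
            covers = diff <= half_width[:, None]  # (n_vox, n_rays)
            occupied = covers.any(axis=0)
            # erode the span edge by two voxels' angular width at mid-wall:
            # the wedge rim is where discretization and noise fray the mask
            mid_r = float(np.median(vox_r))
            erode_bins = max(1, int(np.ceil(2.0 * np.degrees(spacing / mid_r) / bin_width)))
            interior = occupied.copy()
            for _ in range(erode_bins):
                nxt = interior & np.roll(interior, 1) & np.roll(interior, -1)
                if not nxt.any():
                    break  # narrow component: keep the central rays
                interior = nxt
            for b in np.nonzero(interior)[0]:
                radii = np.sort(vox_r[covers[:, b]])
                if radii.size == 0:
                    transmural = False
                    break
                covered = (
                    radii[0] <= endo_r[b] + tolerance_px * spacing
                    and radii[-1] >= epi_r[b] - tolerance_px * spacing
                    and (radii.size == 1 or np.max(np.diff(radii)) <= 2.05 * spacing)
                )
                if not covered:
                    transmural = False
                    break
            if not transmural:
                break
        flags.append(transmural)
    return flags
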