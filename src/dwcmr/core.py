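"""Shared image containers and geometry helpers.

The whole pipeline works on short-axis left-ventricular stacks of three
slices (base, mid, apex).  Images are stored slice-major as ``(n_slices,
ny, nx)`` arrays with isotropic in-plane spacing; physical in-plane
coordinates are millimetres with the origin at the image centre (which the
phantom places at the LV long axis).  Angles are measured counter-clockwise
in index space from a configurable reference ray (the anterior RV-insertion
direction), in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import nibabel as nib
import numpy as np
from skimage.draw import polygon2mask

__all__ = [
    "ImageStack",
    "CineStudy",
    "angle_difference",
    "contour_distance",
    "contours_to_myocardium_mask",
    "load_stack",
    "resample_contour",
    "save_stack",
]


@dataclass
class ImageStack:
    """A 3-slice (or n-slice) short-axis scalar image.

    Parameters
    ----------
    data:
        ``(n_slices, ny, nx)`` array.  Slice 0 is the most basal slice by
        default (the phantom records its own ordering).
    spacing:
        Isotropic in-plane pixel spacing in mm.
    slice_thickness:
        Slice thickness in mm (6 mm in the emulated protocol).
    """

    data: np.ndarray
    spacing: float
    slice_thickness: float = 6.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ImageStack data must be (n_slices, ny, nx)")
        if self.spacing <= 0 or self.slice_thickness <= 0:
            raise ValueError("spacing and slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3."""
        return self.spacing * self.spacing * self.slice_thickness

    def same_geometry(self, other: "ImageStack") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.spacing, other.spacing)
            and np.isclose(self.slice_thickness, other.slice_thickness)
        )

    def xy_grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical in-plane coordinates (mm) of voxel centres.

        Returns ``(x, y)`` arrays of shape ``(ny, nx)`` with the origin at
        the image centre; x increases with column index, y with row index.
        """
        _, ny, nx = self.shape
        cols = (np.arange(nx) - (nx - 1) / 2.0) * self.spacing
        rows = (np.arange(ny) - (ny - 1) / 2.0) * self.spacing
        x, y = np.meshgrid(cols, rows)
        return x, y

    def polar_grid(self, reference_angle_deg: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
        """Radius (mm) and angle (deg, CCW from the reference ray, in [0, 360))."""
        x, y = self.xy_grid()
        r = np.hypot(x, y)
        theta = np.degrees(np.arctan2(y, x)) - reference_angle_deg
        return r, np.mod(theta, 360.0)

    def mm_to_pixel(self, points_mm: np.ndarray) -> np.ndarray:
        """Convert (N, 2) physical ``(x, y)`` mm points to ``(col, row)`` pixels."""
        pts = np.asarray(points_mm, dtype=float)
        _, ny, nx = self.shape
        out = np.empty_like(pts)
        out[..., 0] = pts[..., 0] / self.spacing + (nx - 1) / 2.0
        out[..., 1] = pts[..., 1] / self.spacing + (ny - 1) / 2.0
        return out

    def copy(self) -> "ImageStack":
        return replace(self, data=self.data.copy(), meta=dict(self.meta))


@dataclass
class CineStudy:
    """Multi-phase cine series with per-phase LV endo/epicardial contours.

    ``images`` is ``(n_phases, n_slices, ny, nx)``;  ``contours[phase][slice]``
    is a dict with keys ``"endo"`` and ``"epi"``, each an ``(N, 2)`` array of
    physical ``(x, y)`` points in mm (closed, not repeated at the end).
    Phase 0 is end-diastole.
    """

    images: np.ndarray
    spacing: float
    slice_thickness: float
    contours: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 4:
            raise ValueError("CineStudy images must be (n_phases, n_slices, ny, nx)")
        if len(self.contours) != self.images.shape[0]:
            raise ValueError("one contour set per phase is required")

    @property
    def n_phases(self) -> int:
        return self.images.shape[0]

    @property
    def n_slices(self) -> int:
        return self.images.shape[1]

    def phase_stack(self, phase: int) -> ImageStack:
        return ImageStack(self.images[phase], self.spacing, self.slice_thickness)


def angle_difference(a: np.ndarray, b: float) -> np.ndarray:
    """Minimal absolute angular difference in degrees (result in [0, 180])."""
    d = np.mod(np.asarray(a, dtype=float) - b, 360.0)
    return np.minimum(d, 360.0 - d)


def resample_contour(
    points: np.ndarray,
    n: int,
    mode: str = "angle",
    center: Sequence[float] = (0.0, 0.0),
) -> np.ndarray:
    """Resample a closed contour to ``n`` points.

    ``mode="angle"`` places points at uniform polar angle around ``center``
    (exact material correspondence for radial motion); ``mode="arclength"``
    places them at uniform arc length starting from the point closest to
    angle 0.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ValueError("contour must be an (N>=3, 2) array")
    cx, cy = center
    if mode == "angle":
        theta = np.mod(np.arctan2(pts[:, 1] - cy, pts[:, 0] - cx), 2 * np.pi)
        order = np.argsort(theta)
        theta_s = theta[order]
        r_s = np.hypot(pts[order, 0] - cx, pts[order, 1] - cy)
        theta_ext = np.concatenate([theta_s, theta_s[:1] + 2 * np.pi])
        r_ext = np.concatenate([r_s, r_s[:1]])
        tq = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        rq = np.interp(tq, theta_ext, r_ext, period=2 * np.pi)
        return np.column_stack([cx + rq * np.cos(tq), cy + rq * np.sin(tq)])
    if mode == "arclength":
        closed = np.vstack([pts, pts[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        sq = np.linspace(0.0, total, n, endpoint=False)
        xq = np.interp(sq, s, closed[:, 0])
        yq = np.interp(sq, s, closed[:, 1])
        return np.column_stack([xq, yq])
    raise ValueError(f"unknown resampling mode {mode!r}")


def contour_distance(a: np.ndarray, b: np.ndarray, n: int = 180) -> float:
    """Mean symmetric point-to-contour distance (mm) between two closed contours."""
    pa = resample_contour(a, n)
    pb = resample_contour(b, n)
    d_ab = np.min(np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1), axis=1)
    d_ba = np.min(np.linalg.norm(pb[:, None, :] - pa[None, :, :], axis=-1), axis=1)
    return float((d_ab.mean() + d_ba.mean()) / 2.0)


def contours_to_myocardium_mask(
    contours: Sequence[dict], reference: ImageStack
) -> np.ndarray:
    """Rasterize per-slice endo/epi contours to a boolean myocardium mask.

    Voxels are included by the centre-of-voxel rule: a voxel belongs to the
    myocardium when its centre lies inside the epicardial polygon and outside
    the endocardial polygon.
    """
    if len(contours) != reference.n_slices:
        raise ValueError("need one endo/epi contour pair per slice")
    _, ny, nx = reference.shape
    mask = np.zeros(reference.shape, dtype=bool)
    for s, c in enumerate(contours):
        epi_px = reference.mm_to_pixel(c["epi"])[:, ::-1]  # (row, col)
        endo_px = reference.mm_to_pixel(c["endo"])[:, ::-1]
        inside_epi = polygon2mask((ny, nx), epi_px)
        inside_endo = polygon2mask((ny, nx), endo_px)
        mask[s] = inside_epi & ~inside_endo
    return mask


def save_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as a NIfTI volume (x, y, z axis order)."""
    affine = np.diag([stack.spacing, stack.spacing, stack.slice_thickness, 1.0])
    # store as (nx, ny, n_slices)
    img = nib.Nifti1Image(np.ascontiguousarray(stack.data.T), affine)
    nib.save(img, str(path))


def load_stack(path) -> ImageStack:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    data = np.asarray(img.dataobj, dtype=float).T
    return ImageStack(data, spacing=float(zooms[0]), slice_thickness=float(zooms[2]))
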