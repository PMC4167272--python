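"""Two-step LGE-to-ADC co-registration.

The transform is never estimated between LGE and ADC directly: cine frames
matching each acquisition's cardiac phase are identified first, the
non-rigid transform is estimated between those two cine phases from
corresponding endo/epicardial landmark points, and that transform is then
applied to the LGE image.  This keeps any genuine infarct-delineation
difference between the modalities out of the registration.

Transforms are per-slice 2-D cubic B-spline displacement fields in
physical (mm) coordinates, fitted to landmark pairs by regularized least
squares with a bending-energy (second-difference) penalty.  The stored
displacement is the *backward* map: ``output(x) = image(x + u(x))``, so a
transform for resampling the LGE image into b0-phase space is fitted with
``points_src`` in b0-phase geometry and ``points_dst`` at the same
material points in LGE-phase geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import CineStudy, ImageStack, contour_distance

__all__ = [
    "BSplineTransform",
    "apply_transform",
    "fit_bspline",
    "select_matching_phase",
    "stack_transforms",
]


def _cubic_bspline(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel, support (-2, 2)."""
    a = np.abs(t)
    out = np.zeros_like(a)
    near = a < 1
    out[near] = 2.0 / 3.0 - a[near] ** 2 + 0.5 * a[near] ** 3
    far = (a >= 1) & (a < 2)
    out[far] = (2.0 - a[far]) ** 3 / 6.0
    return out


@dataclass
class _SliceField:
    origin: tuple          # (x0, y0) mm of control node (0, 0)
    grid_spacing: float    # mm
    coeffs: np.ndarray     # (gy, gx, 2) control displacements, mm

    def displacement(self, points_mm: np.ndarray) -> np.ndarray:
        basis = _design_matrix(points_mm, self.origin, self.grid_spacing, self.coeffs.shape[:2])
        return basis @ self.coeffs.reshape(-1, 2)


@dataclass
class BSplineTransform:
    """Per-slice cubic B-spline displacement fields (identity when all zero)."""

    slices: list
    meta: dict = field(default_factory=dict)

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def displacement(self, points_mm: np.ndarray, slice_index: int = 0) -> np.ndarray:
        """Backward displacement (mm) at in-plane points for one slice."""
        f = self.slices[min(slice_index, len(self.slices) - 1)]
        return f.displacement(np.asarray(points_mm, dtype=float))

    def transform(self, points_mm: np.ndarray, slice_index: int = 0) -> np.ndarray:
        pts = np.asarray(points_mm, dtype=float)
        return pts + self.displacement(pts, slice_index)

    def bending_energy(self) -> float:
        """Sum of squared second differences of control displacements (mm²)."""
        total = 0.0
        for f in self.slices:
            c = f.coeffs
            for ax in (0, 1):
                d2 = np.diff(c, n=2, axis=ax)
                total += float(np.sum(d2**2))
        return total


def _design_matrix(points, origin, h, grid_shape):
    pts = np.asarray(points, dtype=float)
    tx = (pts[:, 0] - origin[0]) / h
    ty = (pts[:, 1] - origin[1]) / h
    gy, gx = grid_shape
    bx = _cubic_bspline(tx[:, None] - np.arange(gx)[None, :])  # (n, gx)
    by = _cubic_bspline(ty[:, None] - np.arange(gy)[None, :])  # (n, gy)
    return (by[:, :, None] * bx[:, None, :]).reshape(len(pts), gy * gx)


def _bending_matrix(gy: int, gx: int) -> np.ndarray:
    """Quadratic form of summed squared second differences on the control grid."""
    n = gy * gx
    r = np.zeros((0, n))
    idx = np.arange(n).reshape(gy, gx)
    rows = []
    for j in range(gy - 2):
        for i in range(gx):
            row = np.zeros(n)
            row[idx[j, i]] = 1.0
            row[idx[j + 1, i]] = -2.0
            row[idx[j + 2, i]] = 1.0
            rows.append(row)
    for j in range(gy):
        for i in range(gx - 2):
            row = np.zeros(n)
            row[idx[j, i]] = 1.0
            row[idx[j, i + 1]] = -2.0
            row[idx[j, i + 2]] = 1.0
            rows.append(row)
    d = np.array(rows) if rows else r
    return d.T @ d


def fit_bspline(
    points_src: np.ndarray,
    points_dst: np.ndarray,
    grid_spacing: float = 15.0,
    regularization: float = 1e-3,
) -> BSplineTransform:
    """Fit a single-slice B-spline displacement field mapping src -> dst.

    Least squares on the control displacements with a bending-energy penalty
    of weight ``regularization``; with zero weight the minimum-norm exact
    interpolant is returned.  The landmark residual RMSE (mm) is stored in
    ``meta["residual_rmse_mm"]``.
    """
    src = np.asarray(points_src, dtype=float)
    dst = np.asarray(points_dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("landmark lists must be matching (N, 2) arrays")
    if len(src) < 4:
        raise ValueError("degenerate landmarks: at least 4 corresponding pairs required")
    centered = src - src.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-9 * max(sv[0], 1.0):
        raise ValueError("degenerate landmarks: points are collinear")

    h = float(grid_spacing)
    x0, y0 = src[:, 0].min() - 2 * h, src[:, 1].min() - 2 * h
    gx = int(np.ceil((src[:, 0].max() - x0) / h)) + 3
    gy = int(np.ceil((src[:, 1].max() - y0) / h)) + 3
    a = _design_matrix(src, (x0, y0), h, (gy, gx))
    d = dst - src
    if regularization > 0:
        r = _bending_matrix(gy, gx)
        coef = np.linalg.solve(a.T @ a + regularization * r, a.T @ d)
    else:
        coef, *_ = np.linalg.lstsq(a, d, rcond=None)
    field_ = _SliceField((x0, y0), h, coef.reshape(gy, gx, 2))
    resid = a @ coef - d
    xfm = BSplineTransform([field_])
    xfm.meta["residual_rmse_mm"] = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return xfm


def stack_transforms(transforms: list) -> BSplineTransform:
    """Combine per-slice single-slice transforms into one stack transform."""
    slices = []
    for t in transforms:
        slices.extend(t.slices)
    meta = {"residual_rmse_mm": [t.meta.get("residual_rmse_mm") for t in transforms]}
    return BSplineTransform(slices, meta=meta)


def apply_transform(
    image: ImageStack,
    xfm: BSplineTransform,
    interpolation: str = "linear",
    background: float = 0.0,
) -> ImageStack:
    """Resample an image through the backward displacement field.

    ``output(x) = image(x + u(x))`` per slice; out-of-field voxels take the
    background value.  ``interpolation`` is "linear" (default) or "nearest".
    """
    order = {"linear": 1, "nearest": 0}.get(interpolation)
    if order is None:
        raise ValueError("interpolation must be 'linear' or 'nearest'")
    out = image.copy()
    x, y = image.xy_grid()
    pts = np.column_stack([x.ravel(), y.ravel()])
    for s in range(image.n_slices):
        sample_mm = pts + xfm.displacement(pts, s)
        sample_px = image.mm_to_pixel(sample_mm)
        coords = np.vstack([sample_px[:, 1], sample_px[:, 0]])  # (row, col)
        out.data[s] = ndimage.map_coordinates(
            image.data[s], coords, order=order, cval=background, mode="constant"
        ).reshape(x.shape)
    return out


def _image_dissimilarity(cine: CineStudy, target: ImageStack) -> np.ndarray:
    """Per-phase normalized mean absolute intensity difference."""
    ref = cine.phase_stack(0)
    x, y = ref.xy_grid()
    tgt_px = target.mm_to_pixel(np.column_stack([x.ravel(), y.ravel()]))
    coords = np.vstack([tgt_px[:, 1], tgt_px[:, 0]])
    resampled = np.stack(
        [
            ndimage.map_coordinates(target.data[s], coords, order=1, cval=0.0).reshape(x.shape)
            for s in range(target.n_slices)
        ]
    )

    def _norm(img):
        sd = img.std()
        return (img - img.mean()) / sd if sd > 0 else img - img.mean()

    t_norm = np.stack([_norm(sl) for sl in resampled])
    scores = np.empty(cine.n_phases)
    for p in range(cine.n_phases):
        c_norm = np.stack([_norm(sl) for sl in cine.images[p]])
        scores[p] = np.mean(np.abs(c_norm - t_norm))
    return scores


def _contour_dissimilarity(cine: CineStudy, target_contours: list) -> np.ndarray:
    scores = np.empty(cine.n_phases)
    for p in range(cine.n_phases):
        per_slice = []
        for s, tc in enumerate(target_contours):
            cc = cine.contours[p][s]
            per_slice.append(contour_distance(tc["endo"], cc["endo"]))
            per_slice.append(contour_distance(tc["epi"], cc["epi"]))
        scores[p] = float(np.mean(per_slice))
    return scores


def select_matching_phase(cine: CineStudy, target) -> int:
    """Cardiac phase of the cine series that best matches the target.

    ``target`` is either an :class:`ImageStack` (normalized mean-absolute
    intensity difference after resampling onto the cine grid) or a per-slice
    contour list as produced by manual LV segmentation (mean symmetric
    contour distance).  Ties break toward the earlier phase.
    """
    if cine.n_phases == 0:
        raise ValueError("cine study has no phases")
    if isinstance(target, ImageStack):
        scores = _image_dissimilarity(cine, target)
    else:
        scores = _contour_dissimilarity(cine, target)
    return int(np.argmin(scores))
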