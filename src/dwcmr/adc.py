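"""ADC mapping from b0 and diffusion-weighted stacks.

Per-direction maps come from the two-point monoexponential fit
``ADC = ln(S0 / Sb) / b`` and the trace map is the voxelwise mean of the
three orthogonal directions.  Maps are stored in μm²/ms (1 μm²/ms =
1e-3 mm²/s; the conversion is applied once, at fit time).  Voxels where
either signal is non-positive have no defined fit and are flagged invalid
rather than clamped — clamping would bias regional means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ImageStack

__all__ = ["ADCMap", "fit_adc", "mean_region_adc", "trace_adc"]


@dataclass
class ADCMap:
    """An ADC ImageStack (μm²/ms) with its b-value and validity mask."""

    stack: ImageStack
    b_value: float
    valid: np.ndarray
    directions: tuple = ()

    @property
    def data(self) -> np.ndarray:
        return self.stack.data

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.stack.shape


def fit_adc(b0: ImageStack, bdw: ImageStack, b: float, direction: str = "") -> ADCMap:
    """Two-point monoexponential fit, voxelwise.

    Returns ADC in μm²/ms.  Voxels with ``S0 <= 0`` or ``Sb <= 0`` are
    invalid (value 0, excluded from the validity mask); negative ADC values
    (``Sb > S0``, possible under noise) are kept and flagged valid so that
    regional means remain unbiased.
    """
    if not b0.same_geometry(bdw):
        raise ValueError("b0 and diffusion-weighted stacks have mismatched geometry")
    if b <= 0:
        raise ValueError("b-value must be positive")
    s0 = b0.data
    sb = bdw.data
    valid = (s0 > 0) & (sb > 0)
    adc = np.zeros_like(s0)
    # ln(S0/Sb)/b gives mm²/s with b in s/mm²; x1e3 -> μm²/ms
    adc[valid] = np.log(s0[valid] / sb[valid]) / b * 1e3
    stack = ImageStack(adc, spacing=b0.spacing, slice_thickness=b0.slice_thickness)
    stack.meta["units"] = "um^2/ms"
    return ADCMap(stack, b_value=b, valid=valid, directions=(direction,) if direction else ())


def trace_adc(adc_x: ADCMap, adc_y: ADCMap, adc_z: ADCMap) -> ADCMap:
    """Trace ADC: voxelwise mean of three orthogonal directional maps.

    Validity is the intersection of the inputs' validity masks.
    """
    maps = (adc_x, adc_y, adc_z)
    for m in maps[1:]:
        if not maps[0].stack.same_geometry(m.stack):
            raise ValueError("directional ADC maps have mismatched geometry")
        if not np.isclose(m.b_value, maps[0].b_value):
            raise ValueError("directional ADC maps have mismatched b-values")
    valid = maps[0].valid & maps[1].valid & maps[2].valid
    mean = (adc_x.data + adc_y.data + adc_z.data) / 3.0
    mean = np.where(valid, mean, 0.0)
    stack = ImageStack(mean, spacing=adc_x.stack.spacing, slice_thickness=adc_x.stack.slice_thickness)
    stack.meta["units"] = "um^2/ms"
    dirs = tuple(d for m in maps for d in m.directions)
    return ADCMap(stack, b_value=adc_x.b_value, valid=valid, directions=dirs)


def mean_region_adc(adc_map: ADCMap, mask: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the map over a region (invalid voxels excluded).

    Raises on an empty region (or one with no valid voxels).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != adc_map.shape:
        raise ValueError("region mask has mismatched shape")
    use = mask & adc_map.valid
    if not use.any():
        raise ValueError("region is empty (no valid voxels)")
    vals = adc_map.data[use]
    return float(vals.mean()), float(vals.std(ddof=1)) if vals.size > 1 else 0.0
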