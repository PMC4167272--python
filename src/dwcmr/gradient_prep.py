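"""Diffusion-preparation gradient analysis and design.

Verification toolkit for a motion-compensated diffusion preparation: exact
gradient-moment computation (M0, M1, M2), exact b-value computation, and
the design of a quadra-lobed, first- and second-moment-nulled (M1M2)
waveform under a maximum-gradient and preparation-window constraint.

Units follow scanner conventions: amplitudes in mT/m, times in ms.
Moments are returned in mT·ms^(n+1)/m and b-values in s/mm².  All
integrals are evaluated in closed form over the piecewise-linear effective
gradient (polynomials per segment), so the only error is float rounding.

Refocusing pulses are represented as time markers at which the effective
gradient polarity inverts; RF pulse shapes themselves are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "GradientWaveform",
    "InfeasibleDesignError",
    "TrapezoidLobe",
    "GAMMA_PROTON",
    "b_value",
    "design_quadra_bipolar",
    "moments",
]

GAMMA_PROTON = 2.6752218744e8  # rad / s / T


@dataclass(frozen=True)
class TrapezoidLobe:
    """One trapezoidal gradient lobe (signed amplitude, mT/m; times in ms)."""

    amplitude: float
    ramp_up: float
    flat_top: float
    ramp_down: float

    def __post_init__(self) -> None:
        if min(self.ramp_up, self.flat_top, self.ramp_down) < 0:
            raise ValueError("lobe durations must be non-negative")

    @property
    def duration(self) -> float:
        return self.ramp_up + self.flat_top + self.ramp_down


@dataclass
class GradientWaveform:
    """Contiguous trapezoid lobes plus refocusing-pulse polarity markers.

    The *effective* gradient used for moments and b-value flips sign after
    each refocusing marker (spin phase accrues with inverted polarity after
    a 180° pulse).
    """

    lobes: list
    refocusing_times: list = field(default_factory=list)

    @property
    def duration(self) -> float:
        return sum(lobe.duration for lobe in self.lobes)

    @property
    def max_amplitude(self) -> float:
        if not self.lobes:
            return 0.0
        return max(abs(lobe.amplitude) for lobe in self.lobes)

    def segments(self) -> list[tuple[float, float, float, float]]:
        """Linear pieces ``(t0, t1, g0, g1)`` of the effective gradient.

        Times in ms, amplitudes in mT/m; segments are split at refocusing
        markers and the sign of every piece after a marker is inverted once
        per preceding marker.
        """
        pieces: list[tuple[float, float, float, float]] = []
        t = 0.0
        for lobe in self.lobes:
            a = lobe.amplitude
            if lobe.ramp_up > 0:
                pieces.append((t, t + lobe.ramp_up, 0.0, a))
            t += lobe.ramp_up
            if lobe.flat_top > 0:
                pieces.append((t, t + lobe.flat_top, a, a))
            t += lobe.flat_top
            if lobe.ramp_down > 0:
                pieces.append((t, t + lobe.ramp_down, a, 0.0))
            t += lobe.ramp_down
        markers = sorted(m for m in self.refocusing_times if 0.0 < m < t)
        for m in markers:
            pieces = _split_at(pieces, m)
        out = []
        for t0, t1, g0, g1 in pieces:
            sign = (-1.0) ** sum(1 for m in markers if m <= t0 + 1e-12)
            out.append((t0, t1, sign * g0, sign * g1))
        return out


def _split_at(pieces, t_split):
    out = []
    for t0, t1, g0, g1 in pieces:
        if t0 < t_split < t1:
            gm = g0 + (g1 - g0) * (t_split - t0) / (t1 - t0)
            out.append((t0, t_split, g0, gm))
            out.append((t_split, t1, gm, g1))
        else:
            out.append((t0, t1, g0, g1))
    return out


def _segment_poly(t0: float, t1: float, g0: float, g1: float) -> np.polynomial.Polynomial:
    """G_eff(t) on [t0, t1] as a polynomial in t (global time)."""
    slope = (g1 - g0) / (t1 - t0)
    return np.polynomial.Polynomial([g0 - slope * t0, slope])


def moments(waveform: GradientWaveform, order: int) -> float:
    """Gradient moment M_n = ∫ G_eff(t) t^n dt, closed form (mT·ms^(n+1)/m)."""
    if order not in (0, 1, 2):
        raise ValueError("moment order must be 0, 1 or 2")
    total = 0.0
    tn = np.polynomial.Polynomial.basis(order) if order else np.polynomial.Polynomial([1.0])
    for t0, t1, g0, g1 in waveform.segments():
        p = (_segment_poly(t0, t1, g0, g1) * tn).integ()
        total += p(t1) - p(t0)
    return float(total)


def b_value(waveform: GradientWaveform, gamma: float = GAMMA_PROTON) -> float:
    """Diffusion weighting b = γ² ∫ q(t)² dt with q(t) = ∫₀ᵗ G_eff dτ, in s/mm².

    Exact piecewise-polynomial integration: q is quadratic on each linear
    gradient segment, q² quartic, integrated analytically.
    """
    total = 0.0  # in (mT/m)^2 ms^3
    q_acc = 0.0
    for t0, t1, g0, g1 in waveform.segments():
        g_poly = _segment_poly(t0, t1, g0, g1)
        q_poly = g_poly.integ()
        q_poly = q_poly + (q_acc - q_poly(t0))
        integral = (q_poly**2).integ()
        total += integral(t1) - integral(t0)
        q_acc = q_poly(t1)
    # (mT/m)^2 ms^3 -> T^2 s^3 / m^2 : 1e-6 * 1e-9 ; γ² in (rad/s/T)²
    b_si = gamma**2 * total * 1e-15  # s / m^2
    return float(b_si * 1e-6)  # s / mm^2


class InfeasibleDesignError(ValueError):
    """Raised when the b-target cannot be reached within the constraints."""

    def __init__(self, b_target: float, b_max: float):
        self.b_target = b_target
        self.b_max = b_max
        super().__init__(
            f"b = {b_target:g} s/mm^2 is unreachable within the preparation window; "
            f"maximal achievable b is {b_max:.4g} s/mm^2"
        )


# amplitude pattern of the quadra-lobed M1M2-nulled scheme: four identical,
# equally spaced lobes weighted by the third difference (1, -3, 3, -1), which
# annihilates any quadratic polynomial in the lobe offset and hence nulls
# M0, M1 and M2 exactly, independent of lobe shape.
_QUADRA_PATTERN = np.array([1.0, -3.0, 3.0, -1.0]) / 3.0


def _quadra_waveform(flat_top: float, g_max: float, ramp: float) -> GradientWaveform:
    lobes = [
        TrapezoidLobe(g_max * w, ramp, flat_top, ramp) for w in _QUADRA_PATTERN
    ]
    return GradientWaveform(lobes)


def design_quadra_bipolar(
    b_target: float,
    g_max: float,
    te_prep: float,
    ramp: float = 0.5,
    gamma: float = GAMMA_PROTON,
    b_tol: float = 1e-6,
) -> GradientWaveform:
    """Design a moment-nulled (M0 = M1 = M2 = 0) waveform hitting a b-target.

    The scheme is four contiguous, identically shaped trapezoids with
    amplitudes in the ratio (1, -3, 3, -1)/3 scaled to ``g_max``; the single
    free parameter, the common flat-top duration, is found by monotone
    bisection on the exactly computed b-value.

    Raises
    ------
    InfeasibleDesignError
        If ``b_target`` exceeds the b-value achievable with the longest
        waveform fitting in ``te_prep`` at ``g_max``.
    """
    if b_target < 0 or g_max <= 0 or te_prep <= 0 or ramp <= 0:
        raise ValueError("b_target must be >= 0 and g_max, te_prep, ramp positive")
    if b_target == 0:
        return GradientWaveform([TrapezoidLobe(0.0, ramp, 0.0, ramp)])
    flat_max = te_prep / 4.0 - 2.0 * ramp
    if flat_max < 0:
        raise InfeasibleDesignError(b_target, 0.0)
    b_max = b_value(_quadra_waveform(flat_max, g_max, ramp), gamma)
    if b_target > b_max:
        raise InfeasibleDesignError(b_target, b_max)
    if b_target < b_value(_quadra_waveform(0.0, g_max, ramp), gamma):
        raise ValueError("b_target lies below the minimum reachable with this ramp time")
    lo, hi = 0.0, flat_max
    for _ in range(200):
        mid = (lo + hi) / 2.0
        b_mid = b_value(_quadra_waveform(mid, g_max, ramp), gamma)
        if abs(b_mid - b_target) <= b_tol * b_target:
            lo = hi = mid
            break
        if b_mid < b_target:
            lo = mid
        else:
            hi = mid
    return _quadra_waveform((lo + hi) / 2.0, g_max, ramp)
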