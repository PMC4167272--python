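"""Gradient moments, b-value and the moment-nulled preparation design."""

import numpy as np
import pytest

from dwcmr import (
    GAMMA_PROTON,
    GradientWaveform,
    InfeasibleDesignError,
    TrapezoidLobe,
    b_value,
    design_quadra_bipolar,
    moments,
)


def quadrature_moment(wf: GradientWaveform, order: int, n: int = 4001) -> float:
    """Dense per-segment Simpson quadrature of ∫ G_eff t^n dt (independent oracle)."""
    from scipy.integrate import simpson

    total = 0.0
    for t0, t1, g0, g1 in wf.segments():
        if t1 <= t0:
            continue
        t = np.linspace(t0, t1, n)
        g = g0 + (g1 - g0) * (t - t0) / (t1 - t0)
        total += simpson(g * t**order, x=t)
    return float(total)


def quadrature_b(wf: GradientWaveform, gamma: float = GAMMA_PROTON, n: int = 4001) -> float:
    from scipy.integrate import cumulative_trapezoid, simpson

    total = 0.0
    q0 = 0.0
    for t0, t1, g0, g1 in wf.segments():
        if t1 <= t0:
            continue
        t = np.linspace(t0, t1, n)
        g = g0 + (g1 - g0) * (t - t0) / (t1 - t0)
        q = q0 + cumulative_trapezoid(g, t, initial=0.0)
        total += simpson(q**2, x=t)
        q0 = q[-1]
    return float(gamma**2 * total * 1e-15 * 1e-6)


def random_waveform(rng) -> GradientWaveform:
    lobes = [
        TrapezoidLobe(
            amplitude=rng.uniform(-40, 40),
            ramp_up=rng.uniform(0.1, 1.0),
            flat_top=rng.uniform(0.0, 8.0),
            ramp_down=rng.uniform(0.1, 1.0),
        )
        for _ in range(rng.integers(1, 6))
    ]
    wf = GradientWaveform(lobes)
    if rng.random() < 0.5:
        wf.refocusing_times = sorted(rng.uniform(0, wf.duration, rng.integers(1, 3)).tolist())
    return wf


class TestMoments:
    def test_single_trapezoid_area(self):
        # M0 of a symmetric trapezoid = G * (flat + ramp)
        wf = GradientWaveform([TrapezoidLobe(25.0, 1.0, 10.0, 1.0)])
        assert moments(wf, 0) == pytest.approx(25.0 * 11.0, rel=1e-12)

    def test_bipolar_pair_has_zero_area(self):
        wf = GradientWaveform(
            [TrapezoidLobe(30.0, 0.5, 5.0, 0.5), TrapezoidLobe(-30.0, 0.5, 5.0, 0.5)]
        )
        assert moments(wf, 0) == pytest.approx(0.0, abs=1e-10)

    def test_refocusing_marker_inverts_polarity(self):
        # a marker in the middle of a constant lobe makes the two halves cancel
        wf = GradientWaveform([TrapezoidLobe(20.0, 0.0, 10.0, 0.0)], refocusing_times=[5.0])
        assert moments(wf, 0) == pytest.approx(0.0, abs=1e-10)

    def test_invalid_order_rejected(self):
        wf = GradientWaveform([TrapezoidLobe(10.0, 1.0, 1.0, 1.0)])
        with pytest.raises(ValueError):
            moments(wf, 3)

    def test_closed_form_matches_dense_quadrature(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            wf = random_waveform(rng)
            for order in (0, 1, 2):
                exact = moments(wf, order)
                approx = quadrature_moment(wf, order)
                scale = max(abs(exact), 40.0 * wf.duration ** (order + 1))
                assert abs(exact - approx) <= 1e-8 * scale


class TestBValue:
    def test_zero_amplitude_gives_zero_b(self):
        wf = GradientWaveform([TrapezoidLobe(0.0, 1.0, 10.0, 1.0)])
        assert b_value(wf) == 0.0

    def test_stejskal_tanner_closed_form(self):
        # rectangular pair: b = gamma^2 G^2 delta^2 (Delta - delta/3)
        g_mt, delta, gap = 30.0, 12.0, 20.0  # mT/m, ms, ms
        wf = GradientWaveform(
            [
                TrapezoidLobe(g_mt, 0.0, delta, 0.0),
                TrapezoidLobe(0.0, 0.0, gap, 0.0),
                TrapezoidLobe(-g_mt, 0.0, delta, 0.0),
            ]
        )
        big_delta = delta + gap
        expected = (
            GAMMA_PROTON**2 * (g_mt * 1e-3) ** 2 * (delta * 1e-3) ** 2
            * ((big_delta - delta / 3.0) * 1e-3)
        ) * 1e-6  # s/m^2 -> s/mm^2
        assert b_value(wf) == pytest.approx(expected, rel=1e-10)
        assert b_value(wf) == pytest.approx(quadrature_b(wf), rel=1e-6)

    def test_quadratic_amplitude_scaling(self):
        rng = np.random.default_rng(7)
        wf = random_waveform(rng)
        doubled = GradientWaveform(
            [TrapezoidLobe(2 * l.amplitude, l.ramp_up, l.flat_top, l.ramp_down) for l in wf.lobes],
            refocusing_times=list(wf.refocusing_times),
        )
        assert b_value(doubled) == pytest.approx(4.0 * b_value(wf), rel=1e-12)

    def test_time_shift_invariance(self):
        wf = design_quadra_bipolar(200.0, 40.0, 80.0)
        shifted = GradientWaveform(
            [TrapezoidLobe(0.0, 0.0, 7.5, 0.0)] + list(wf.lobes)
        )
        assert b_value(shifted) == pytest.approx(b_value(wf), rel=1e-9)
        # M1, M2 of a fully nulled waveform stay null under time shift
        for order in (1, 2):
            assert abs(moments(shifted, order)) < 1e-6


class TestDesign:
    def test_study_protocol_design_is_feasible(self):
        wf = design_quadra_bipolar(400.0, 43.0, 105.0)
        assert wf.duration <= 105.0
        assert wf.max_amplitude <= 43.0 + 1e-9
        assert b_value(wf) == pytest.approx(400.0, rel=5e-3)
        for order in (0, 1, 2):
            tol = 1e-9 * 43.0 * 105.0 ** (order + 1)
            assert abs(moments(wf, order)) < tol

    def test_zero_b_target_returns_silence(self):
        wf = design_quadra_bipolar(0.0, 43.0, 105.0)
        assert wf.max_amplitude == 0.0
        assert b_value(wf) == 0.0

    def test_infeasible_window_raises_with_achievable_bound(self):
        with pytest.raises(InfeasibleDesignError) as exc:
            design_quadra_bipolar(400.0, 43.0, 5.0)
        b_max = exc.value.b_max
        # brute-force confirmation: sweep flat-top durations up to the window
        from dwcmr.gradient_prep import _quadra_waveform

        flats = np.linspace(0.0, 5.0 / 4.0 - 1.0, 200)
        best = max(b_value(_quadra_waveform(f, 43.0, 0.5)) for f in flats)
        assert b_max == pytest.approx(best, rel=1e-6)
        assert b_max < 400.0
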