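"""Ground-truthed digital left-ventricular phantom.

Emulates the acquisitions of a 3-slice short-axis chronic-infarct CMR
study: one non-diffusion-weighted image (b0), three orthogonal
diffusion-weighted images at b = 400 s/mm^2 (2.1 mm in-plane), an
LGE-like hyperenhancement image (1.3 mm, generated in a different cardiac
phase so the registration stage has real work), and a 35-phase cine series
(1.4 mm) with analytic endo/epicardial contours.  Slice thickness is 6 mm.

The myocardium is an annulus per slice.  A transmural anteroseptal wedge
(the LAD territory, ~11% of the imaged LV volume by default) carries an
elevated apparent diffusion coefficient and near-zero wall excursion; the
remainder moves radially with ~8.3 mm endocardial excursion.  Magnitude-MR
(Rician) noise is added at a configurable SNR.

Ground truth (true ADC map, myocardium/infarct masks on every grid, the
analytic motion model and the inter-phase warp) is carried alongside the
images so every downstream stage can be scored against it.

Infarct ADC is not spatially flat: it follows a smooth unimodal angular
profile whose mean is the configured infarct ADC (default 2.4 μm²/ms,
peak ≈3.1, edge ≈1.7).  Chronic infarcts have a hot core, and the
half-maximum rule depends on it: a flat 2.4 against a 1.4 remote would put
the 50%-of-max cutoff below remote myocardium and the criterion would be
meaningless on ADC maps.  The default amplitude places the half-of-peak
level midway between the infarct edge and remote myocardium, the maximally
robust geometry for the two-stage rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import CineStudy, ImageStack, angle_difference

__all__ = [
    "PhantomConfig",
    "PhantomStudy",
    "add_rician_noise",
    "generate_phantom",
    "simulate_cine",
]

# cine display intensities (arbitrary units)
_CINE_MYO = 80.0
_CINE_BLOOD = 140.0
_CONTOUR_POINTS = 200


@dataclass
class PhantomConfig:
    """Everything the phantom needs; defaults are the emulated study conditions."""

    # grids (pixels per slice, isotropic in-plane spacing in mm)
    n_pixels_dwi: int = 64
    spacing_dwi: float = 2.1
    n_pixels_lge: int = 104
    spacing_lge: float = 1.3
    n_pixels_cine: int = 96
    spacing_cine: float = 1.4
    slice_thickness: float = 6.0

    # LV geometry at end-diastole, base -> apex (slice 0 = base)
    endo_radii: tuple = (17.0, 15.0, 11.0)
    epi_radii: tuple = (28.0, 26.0, 22.0)

    # infarct wedge (angles CCW from the anterior reference ray, degrees)
    infarct_center_deg: float = 50.0
    infarct_extent_deg: float = 40.0
    infarct_slices: tuple = (0, 1, 2)
    infarct_transmural: bool = True
    infarct_transmural_fraction: float = 1.0  # endo-side wall fraction if not transmural
    infarct_fraction_target: float | None = None  # % of imaged LV; overrides extent

    # diffusion / signal model
    remote_adc: float = 1.4          # μm²/ms
    infarct_adc: float = 2.4         # μm²/ms (spatial mean over the wedge)
    infarct_adc_heterogeneity: float = 1.4  # peak-to-edge amplitude of the wedge profile
    blood_adc: float = 3.0
    b_value: float = 400.0           # s/mm²
    s0_myo: float = 100.0
    s0_blood: float = 120.0

    # LGE intensities (arbitrary units; remote myocardium nulled-ish)
    lge_remote: float = 15.0
    lge_infarct: float = 90.0
    lge_blood: float = 45.0

    # motion model
    n_phases: int = 35
    remote_excursion: float = 8.3    # mm, endocardial, peak over the cycle
    infarct_excursion: float = 0.9   # mm
    akinetic_margin_deg: float = 55.0
    motion_transition_deg: float = 20.0
    epi_excursion_fraction: float = 0.35
    dwi_phase: int = 27              # quiescent diastolic phase of the DWI/b0 acquisition
    lge_phase: int = 10              # phase of the LGE acquisition (deformed geometry)

    # noise / bookkeeping
    snr: float | None = 50.0         # None or inf -> noise free
    seed: int = 0
    reference_angle_deg: float = 0.0
    base_slice_first: bool = True

    def __post_init__(self) -> None:
        if len(self.endo_radii) != len(self.epi_radii):
            raise ValueError("endo_radii and epi_radii must have equal length")
        for e, p in zip(self.endo_radii, self.epi_radii):
            if e <= 0 or p <= 0:
                raise ValueError("radii must be positive")
            if e >= p:
                raise ValueError("endocardial radius must be below epicardial radius")
        if self.infarct_fraction_target is not None:
            extent = _extent_for_fraction(self, self.infarct_fraction_target)
            object.__setattr__(self, "infarct_extent_deg", extent)
        if not (0.0 < self.infarct_extent_deg <= 360.0):
            raise ValueError("infarct angular extent must lie in (0, 360] degrees")
        if any(s not in range(self.n_slices) for s in self.infarct_slices):
            raise ValueError("infarct slice span exceeds the imaged myocardium")
        if self.infarct_adc <= self.remote_adc:
            raise ValueError("infarct ADC must exceed remote ADC")
        if self.remote_excursion < 0 or self.infarct_excursion < 0:
            raise ValueError("excursions must be non-negative")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.n_phases < 2:
            raise ValueError("at least two cardiac phases are required")

    @property
    def n_slices(self) -> int:
        return len(self.endo_radii)

    @property
    def noise_free(self) -> bool:
        return self.snr is None or math.isinf(self.snr)

    def infarct_fraction(self) -> float:
        """Infarct percentage of the imaged LV volume at the acquisition phase.

        Computed analytically (angular integration of the annulus), so the
        rasterized ground-truth mask should match it up to discretization.
        """
        return analytic_infarct_fraction(self)


def analytic_infarct_fraction(config: "PhantomConfig") -> float:
    theta = np.linspace(0.0, 360.0, 2881)
    theta_rad = np.radians(theta)
    total = 0.0
    inf_total = 0.0
    half = config.infarct_extent_deg / 2.0
    in_sector = angle_difference(theta, config.infarct_center_deg) <= half
    for s in range(config.n_slices):
        endo, epi = wall_radii(config, theta, s, config.dwi_phase)
        density = (epi**2 - endo**2) / 2.0  # annulus area per radian
        total += np.trapezoid(density, theta_rad)
        if s in config.infarct_slices:
            if config.infarct_transmural:
                ri = epi
            else:
                ri = endo + config.infarct_transmural_fraction * (epi - endo)
            inf_density = np.where(in_sector, (ri**2 - endo**2) / 2.0, 0.0)
            inf_total += np.trapezoid(inf_density, theta_rad)
    return 100.0 * inf_total / total


def _extent_for_fraction(config: PhantomConfig, fraction_pct: float) -> float:
    from scipy.optimize import brentq

    def objective(extent: float) -> float:
        trial = replace(config, infarct_fraction_target=None, infarct_extent_deg=extent)
        return analytic_infarct_fraction(trial) - fraction_pct

    if objective(360.0) < 0:
        raise ValueError("requested infarct fraction exceeds the spanned myocardium")
    return float(brentq(objective, 1e-3, 360.0, xtol=1e-6))


# ---------------------------------------------------------------- motion model


def _contraction(config: PhantomConfig, phase: int | np.ndarray) -> np.ndarray:
    """Normalized contraction waveform: 0 at end-diastole (phase 0), 1 at end-systole."""
    p = np.asarray(phase, dtype=float)
    return np.sin(np.pi * p / (config.n_phases - 1)) ** 2


def _akinetic_weight(config: PhantomConfig, theta_deg: np.ndarray) -> np.ndarray:
    """1 inside the hypokinetic zone (infarct sector + margin), 0 in remote wall."""
    d = angle_difference(theta_deg, config.infarct_center_deg)
    d = np.clip(d - config.infarct_extent_deg / 2.0, 0.0, None)
    w = np.zeros_like(d)
    inner = d <= config.akinetic_margin_deg
    w[inner] = 1.0
    t = config.motion_transition_deg
    if t > 0:
        ramp = (~inner) & (d < config.akinetic_margin_deg + t)
        w[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - config.akinetic_margin_deg) / t))
    return w


def endocardial_excursion(config: PhantomConfig, theta_deg, slice_index: int) -> np.ndarray:
    """Peak endocardial excursion (mm) along the ray at ``theta_deg``."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    if slice_index in config.infarct_slices:
        w = _akinetic_weight(config, theta)
    else:
        w = np.zeros_like(theta)
    return config.remote_excursion + (config.infarct_excursion - config.remote_excursion) * w


def wall_radii(
    config: PhantomConfig, theta_deg, slice_index: int, phase: int
) -> tuple[np.ndarray, np.ndarray]:
    """Endo/epi radii (mm) along rays at ``theta_deg`` for one slice and phase."""
    theta = np.atleast_1d(np.asarray(theta_deg, dtype=float))
    exc = endocardial_excursion(config, theta, slice_index)
    m = float(_contraction(config, phase))
    endo = config.endo_radii[slice_index] - exc * m
    epi = config.epi_radii[slice_index] - config.epi_excursion_fraction * exc * m
    return endo, epi


def _contour(config: PhantomConfig, slice_index: int, phase: int, which: str) -> np.ndarray:
    theta = np.linspace(0.0, 360.0, _CONTOUR_POINTS, endpoint=False)
    endo, epi = wall_radii(config, theta, slice_index, phase)
    r = endo if which == "endo" else epi
    a = np.radians(theta + config.reference_angle_deg)
    return np.column_stack([r * np.cos(a), r * np.sin(a)])


def phase_contours(config: PhantomConfig, phase: int) -> list[dict]:
    """Per-slice endo/epi contours (mm) at one cardiac phase."""
    return [
        {
            "endo": _contour(config, s, phase, "endo"),
            "epi": _contour(config, s, phase, "epi"),
        }
        for s in range(config.n_slices)
    ]


# ------------------------------------------------------------------ raster maps


def _grid(config: PhantomConfig, n_pixels: int, spacing: float) -> ImageStack:
    data = np.zeros((config.n_slices, n_pixels, n_pixels))
    return ImageStack(data, spacing=spacing, slice_thickness=config.slice_thickness)


def myocardium_mask(config: PhantomConfig, geometry: ImageStack, phase: int) -> np.ndarray:
    """Boolean myocardium mask on a grid, centre-of-voxel inclusion."""
    r, theta = geometry.polar_grid(config.reference_angle_deg)
    mask = np.zeros(geometry.shape, dtype=bool)
    for s in range(config.n_slices):
        endo, epi = wall_radii(config, theta.ravel(), s, phase)
        m = (r.ravel() >= endo) & (r.ravel() <= epi)
        mask[s] = m.reshape(r.shape)
    return mask


def cavity_mask(config: PhantomConfig, geometry: ImageStack, phase: int) -> np.ndarray:
    r, theta = geometry.polar_grid(config.reference_angle_deg)
    mask = np.zeros(geometry.shape, dtype=bool)
    for s in range(config.n_slices):
        endo, _ = wall_radii(config, theta.ravel(), s, phase)
        mask[s] = (r.ravel() < endo).reshape(r.shape)
    return mask


def infarct_mask(config: PhantomConfig, geometry: ImageStack, phase: int) -> np.ndarray:
    """Boolean ground-truth infarct mask on a grid (subset of the myocardium)."""
    myo = myocardium_mask(config, geometry, phase)
    r, theta = geometry.polar_grid(config.reference_angle_deg)
    in_sector = angle_difference(theta, config.infarct_center_deg) <= config.infarct_extent_deg / 2.0
    mask = np.zeros(geometry.shape, dtype=bool)
    for s in config.infarct_slices:
        m = myo[s] & in_sector
        if not config.infarct_transmural:
            endo, epi = wall_radii(config, theta.ravel(), s, phase)
            depth_limit = endo + config.infarct_transmural_fraction * (epi - endo)
            m &= (r.ravel() <= depth_limit).reshape(r.shape)
        mask[s] = m
    return mask


def _infarct_adc_values(config: PhantomConfig, theta_deg: np.ndarray) -> np.ndarray:
    """Unimodal angular ADC profile over the wedge, mean-centred to the configured mean."""
    u = angle_difference(theta_deg, config.infarct_center_deg) / (config.infarct_extent_deg / 2.0)
    u = np.clip(u, 0.0, 1.0)
    bump = (1.0 - u * u) ** 2
    return bump  # centring against the voxel mean happens at map build time


def true_adc_map(config: PhantomConfig, geometry: ImageStack, phase: int) -> tuple[ImageStack, np.ndarray, np.ndarray]:
    """Ground-truth trace-ADC map (μm²/ms) plus myocardium and infarct masks."""
    myo = myocardium_mask(config, geometry, phase)
    inf = infarct_mask(config, geometry, phase)
    cav = cavity_mask(config, geometry, phase)
    _, theta = geometry.polar_grid(config.reference_angle_deg)
    adc = np.zeros(geometry.shape)
    adc[myo] = config.remote_adc
    adc[cav] = config.blood_adc
    if inf.any():
        theta3 = np.broadcast_to(theta, geometry.shape)
        bump = _infarct_adc_values(config, theta3[inf])
        adc[inf] = config.infarct_adc + config.infarct_adc_heterogeneity * (bump - bump.mean())
    out = replace(geometry, data=adc)
    out.meta["units"] = "um^2/ms"
    return out, myo, inf


def _s0_map(config: PhantomConfig, geometry: ImageStack, phase: int) -> np.ndarray:
    myo = myocardium_mask(config, geometry, phase)
    cav = cavity_mask(config, geometry, phase)
    s0 = np.zeros(geometry.shape)
    s0[myo] = config.s0_myo
    s0[cav] = config.s0_blood
    return s0


def _lge_image(config: PhantomConfig, geometry: ImageStack, phase: int) -> np.ndarray:
    myo = myocardium_mask(config, geometry, phase)
    inf = infarct_mask(config, geometry, phase)
    cav = cavity_mask(config, geometry, phase)
    img = np.zeros(geometry.shape)
    img[myo] = config.lge_remote
    img[cav] = config.lge_blood
    img[inf] = config.lge_infarct
    return img


# ----------------------------------------------------------------------- noise


def add_rician_noise(image: ImageStack, snr: float, seed: int, reference: float | None = None) -> ImageStack:
    """Magnitude-MR noise: out = |signal + complex Gaussian|, sigma = reference / snr.

    ``reference`` defaults to the maximum image intensity; the phantom passes
    the remote-myocardium b0 amplitude so SNR is defined against tissue.
    """
    if snr <= 0:
        raise ValueError("SNR must be positive")
    out = image.copy()
    if math.isinf(snr):
        return out
    ref = float(reference) if reference is not None else float(np.max(np.abs(image.data)))
    sigma = ref / snr
    rng = np.random.default_rng(seed)
    re = image.data + rng.normal(0.0, sigma, image.shape)
    im = rng.normal(0.0, sigma, image.shape)
    out.data = np.hypot(re, im)
    out.meta["noise_sigma"] = sigma
    return out


# ------------------------------------------------------------------------ cine


def simulate_cine(config: PhantomConfig) -> CineStudy:
    """Multi-phase cine with analytic contours; phase 0 is end-diastole."""
    geom = _grid(config, config.n_pixels_cine, config.spacing_cine)
    images = np.zeros((config.n_phases, config.n_slices, config.n_pixels_cine, config.n_pixels_cine))
    contours = []
    for p in range(config.n_phases):
        myo = myocardium_mask(config, geom, p)
        cav = cavity_mask(config, geom, p)
        frame = np.zeros(geom.shape)
        frame[myo] = _CINE_MYO
        frame[cav] = _CINE_BLOOD
        images[p] = frame
        contours.append(phase_contours(config, p))
    cine = CineStudy(
        images,
        spacing=config.spacing_cine,
        slice_thickness=config.slice_thickness,
        contours=contours,
    )
    if not config.noise_free:
        rng_seed = np.random.SeedSequence([config.seed, 4]).generate_state(1)[0]
        stack = ImageStack(
            images.reshape(-1, config.n_pixels_cine, config.n_pixels_cine),
            spacing=config.spacing_cine,
            slice_thickness=config.slice_thickness,
        )
        noisy = add_rician_noise(stack, config.snr, int(rng_seed), reference=_CINE_MYO)
        cine.images = noisy.data.reshape(images.shape)
    return cine


# --------------------------------------------------------------------- phantom


@dataclass
class PhantomStudy:
    """One simulated subject: images plus complete ground truth."""

    config: PhantomConfig
    b0: ImageStack
    dwi: tuple  # three directional ImageStacks
    lge: ImageStack
    cine: CineStudy
    true_adc: ImageStack          # DWI grid, acquisition (b0) phase
    true_myocardium: np.ndarray   # DWI grid
    true_infarct: np.ndarray      # DWI grid
    lge_true_myocardium: np.ndarray  # LGE grid, at the b0 (target) phase
    lge_true_infarct: np.ndarray     # LGE grid, at the b0 phase
    meta: dict = field(default_factory=dict)

    @property
    def dwi_phase(self) -> int:
        return self.config.dwi_phase

    @property
    def lge_phase(self) -> int:
        return self.config.lge_phase

    def contours(self, phase: int) -> list[dict]:
        return phase_contours(self.config, phase)

    def excursion(self, theta_deg, slice_index: int) -> np.ndarray:
        """Ground-truth peak endocardial excursion along rays (mm)."""
        return endocardial_excursion(self.config, theta_deg, slice_index)

    def true_warp(self, points_mm: np.ndarray, slice_index: int, from_phase: int, to_phase: int) -> np.ndarray:
        """Map in-plane points (mm) from one phase's geometry to another's.

        Material points keep their polar angle and their normalized transmural
        depth; depth is extrapolated linearly outside the wall so the map is
        smooth across the contours.
        """
        pts = np.asarray(points_mm, dtype=float)
        cfg = self.config
        x, y = pts[:, 0], pts[:, 1]
        r = np.hypot(x, y)
        theta = np.degrees(np.arctan2(y, x)) - cfg.reference_angle_deg
        e0, p0 = wall_radii(cfg, theta, slice_index, from_phase)
        e1, p1 = wall_radii(cfg, theta, slice_index, to_phase)
        depth = (r - e0) / (p0 - e0)
        r_new = e1 + depth * (p1 - e1)
        a = np.radians(theta + cfg.reference_angle_deg)
        return np.column_stack([r_new * np.cos(a), r_new * np.sin(a)])


def generate_phantom(config: PhantomConfig) -> PhantomStudy:
    """Build one fully ground-truthed subject; deterministic for a given seed."""
    ss = np.random.SeedSequence(config.seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]

    dwi_geom = _grid(config, config.n_pixels_dwi, config.spacing_dwi)
    lge_geom = _grid(config, config.n_pixels_lge, config.spacing_lge)

    adc_true, myo, inf = true_adc_map(config, dwi_geom, config.dwi_phase)
    s0 = _s0_map(config, dwi_geom, config.dwi_phase)
    b0 = replace(dwi_geom, data=s0.copy())
    attenuation = np.exp(-config.b_value * adc_true.data * 1e-3)  # μm²/ms -> mm²/s
    dwi_clean = [replace(dwi_geom, data=s0 * attenuation) for _ in range(3)]

    lge_clean = replace(lge_geom, data=_lge_image(config, lge_geom, config.lge_phase))

    if config.noise_free:
        b0_img, dwi_imgs, lge_img = b0, tuple(dwi_clean), lge_clean
    else:
        b0_img = add_rician_noise(b0, config.snr, child_seeds[0], reference=config.s0_myo)
        dwi_imgs = tuple(
            add_rician_noise(d, config.snr, child_seeds[1 + i], reference=config.s0_myo)
            for i, d in enumerate(dwi_clean)
        )
        lge_img = add_rician_noise(lge_clean, config.snr, child_seeds[4], reference=config.lge_infarct)

    cine = simulate_cine(config)

    lge_myo_b0 = myocardium_mask(config, lge_geom, config.dwi_phase)
    lge_inf_b0 = infarct_mask(config, lge_geom, config.dwi_phase)

    study = PhantomStudy(
        config=config,
        b0=b0_img,
        dwi=dwi_imgs,
        lge=lge_img,
        cine=cine,
        true_adc=adc_true,
        true_myocardium=myo,
        true_infarct=inf,
        lge_true_myocardium=lge_myo_b0,
        lge_true_infarct=lge_inf_b0,
    )
    study.meta["infarct_fraction_pct"] = config.infarct_fraction()
    return study
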