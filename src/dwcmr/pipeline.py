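"""End-to-end study replica on a phantom cohort.

Runs the full contrast-free infarct characterization on a seeded cohort of
digital LV phantoms, in the fixed stage order: ADC mapping -> cardiac-phase
matching -> cine-to-cine B-spline registration applied to LGE -> threshold
and FWHM infarct classification on both modalities -> volume percentage ->
AHA segment scoring and chord-based wall motion -> agreement statistics.
Human reviewers are replicated as seeded perturbations of the remote-ROI
placement and of the FWHM seed voxels (two reviewers plus one repeat by
reviewer 1); this probes the pipeline's sensitivity to operator input, not
human behaviour.

The report bundles regional means (ADC and wall motion), volume-agreement
statistics (ICC, R², Bland-Altman bias, Wilcoxon), and segment-location
statistics (contingency tables, Cohen's kappa, diagnostic metrics against
LGE as gold standard), together with ground-truth columns a real study
does not have.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from . import agreement as ag
from .adc import ADCMap, fit_adc, mean_region_adc, trace_adc
from .aha import assign_segments_stack, score_segments, segment_for_angles
from .core import ImageStack, angle_difference, contours_to_myocardium_mask, resample_contour
from .phantom import PhantomConfig, PhantomStudy, generate_phantom
from .quantify import InfarctMask, fwhm_classify, infarct_volume_pct, threshold_classify, transmurality
from .register import apply_transform, fit_bspline, select_matching_phase, stack_transforms
from .wallmotion import chord_displacement, classify_akinetic

__all__ = ["StudyConfig", "run_study", "sample_cohort", "simulate_reviewers", "write_report"]

_AHA_BOUNDARIES = np.array([0.0, 60.0, 90.0, 120.0, 180.0, 240.0, 270.0, 300.0])


@dataclass
class StudyConfig:
    """Cohort design, classifier settings and reviewer-simulation settings."""

    cohort_size: int = 11
    master_seed: int = 0
    phantom_template: PhantomConfig = field(default_factory=PhantomConfig)

    # cohort variation (per-subject draws around the template)
    infarct_fraction_mean: float = 11.0     # % of imaged LV (Table-like 11 ± 4)
    infarct_fraction_sd: float = 3.5
    infarct_fraction_range: tuple = (4.0, 18.0)
    infarct_center_sd_deg: float = 6.0
    # tissue ADC means are the study's group values for every subject; the
    # cohort varies anatomy, infarct size/position and noise realization
    remote_adc_sd: float = 0.0
    infarct_adc_sd: float = 0.0
    radii_jitter_sd: float = 0.03
    # keep wedge edges clear of AHA boundaries: slivers below one voxel's
    # angular footprint (and single-voxel noise fringes at the wedge edge)
    # make the any-voxel segment rule grid-dependent
    segment_boundary_margin_deg: float = 12.0

    # classifiers
    threshold_n_sd: float = 6.0
    fwhm_fraction: float = 0.5
    akinesis_cutoff_mm: float = 3.0

    # remote ROI: lateral wall of the most basal slice
    remote_roi_center_deg: float = 270.0
    remote_roi_width_deg: float = 60.0

    # reviewer perturbations
    roi_center_jitter_deg: float = 10.0
    seed_jitter_px: int = 1

    # registration
    landmarks_per_contour: int = 50
    landmark_mode: str = "angle"           # "angle" | "arclength"
    bspline_grid_spacing: float = 10.0
    bspline_regularization: float = 1e-3

    n_chords: int = 100

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort size must be >= 1")
        if self.threshold_n_sd <= 0 or self.fwhm_fraction <= 0 or self.akinesis_cutoff_mm <= 0:
            raise ValueError("classifier cutoffs must be positive")


def sample_cohort(config: StudyConfig) -> list[PhantomConfig]:
    """Seeded per-subject phantom configs around the template conditions."""
    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 1]))
    tmpl = config.phantom_template
    out = []
    for i in range(config.cohort_size):
        frac = float(np.clip(
            rng.normal(config.infarct_fraction_mean, config.infarct_fraction_sd),
            *config.infarct_fraction_range,
        ))
        # redraw the wedge centre until both edges are clear of AHA boundaries
        extent = replace(tmpl, infarct_fraction_target=frac).infarct_extent_deg
        for _ in range(200):
            center = rng.normal(tmpl.infarct_center_deg, config.infarct_center_sd_deg)
            edges = np.array([center - extent / 2.0, center + extent / 2.0])
            d = np.min(
                np.abs((edges[:, None] - _AHA_BOUNDARIES[None, :] + 180.0) % 360.0 - 180.0),
                axis=1,
            )
            if np.all(d >= config.segment_boundary_margin_deg):
                break
        scale = 1.0 + rng.normal(0.0, config.radii_jitter_sd)
        cfg = replace(
            tmpl,
            seed=int(np.random.SeedSequence([config.master_seed, 2, i]).generate_state(1)[0] % (2**31)),
            infarct_fraction_target=frac,
            infarct_center_deg=float(np.mod(center, 360.0)),
            remote_adc=float(rng.normal(tmpl.remote_adc, config.remote_adc_sd)),
            infarct_adc=float(rng.normal(tmpl.infarct_adc, config.infarct_adc_sd)),
            endo_radii=tuple(r * scale for r in tmpl.endo_radii),
            epi_radii=tuple(r * scale for r in tmpl.epi_radii),
        )
        out.append(cfg)
    return out


# ------------------------------------------------------- per-subject analysis


@dataclass
class SubjectWorkspace:
    """Reviewer-independent intermediates for one subject."""

    study: PhantomStudy
    adc: ADCMap
    lge_registered: ImageStack
    myo_dwi: np.ndarray
    myo_lge: np.ndarray          # analyzed LGE myocardium (endo-eroded)
    labels_dwi: np.ndarray
    labels_lge: np.ndarray
    rwm: "object"
    chord_labels: np.ndarray
    matched_b0_phase: int
    matched_lge_phase: int
    registration_rmse_mm: list


def _erode_endocardial_ring(myo: np.ndarray, contours, reference: ImageStack,
                            iterations: int = 2) -> np.ndarray:
    """Remove the pixel ring adjacent to the blood pool.

    Backward-warp interpolation at the blood/myocardium interface produces
    intermediate intensities that a noise-free threshold would misread as
    enhancement (worst where the motion field varies quickly and the fitted
    spline's local residual is largest); the subendocardial ring is
    therefore excluded from the analyzed LGE myocardium (numerator and
    denominator alike).
    """
    out = np.zeros_like(myo)
    struct = ndimage.generate_binary_structure(2, 1)
    for s in range(myo.shape[0]):
        endo_px = reference.mm_to_pixel(np.asarray(contours[s]["endo"]))[:, ::-1]
        from skimage.draw import polygon2mask

        cavity = polygon2mask(myo.shape[1:], endo_px)
        ring = ndimage.binary_dilation(cavity, structure=struct, iterations=iterations)
        out[s] = myo[s] & ~ring
    return out


def prepare_subject(study: PhantomStudy, config: StudyConfig) -> SubjectWorkspace:
    """Reviewer-independent stages: ADC fit, phase match, registration, RWM."""
    cfg = study.config
    maps = [fit_adc(study.b0, d, cfg.b_value, direction=ax) for d, ax in zip(study.dwi, "xyz")]
    adc = trace_adc(*maps)

    # two-step co-registration (never LGE -> ADC directly)
    b0_contours = study.contours(cfg.dwi_phase)
    lge_contours = study.contours(cfg.lge_phase)
    p_b0 = select_matching_phase(study.cine, b0_contours)
    p_lge = select_matching_phase(study.cine, lge_contours)
    per_slice = []
    for s in range(cfg.n_slices):
        src_pts = []
        dst_pts = []
        for which in ("endo", "epi"):
            src_pts.append(resample_contour(
                study.cine.contours[p_b0][s][which], config.landmarks_per_contour,
                mode=config.landmark_mode))
            dst_pts.append(resample_contour(
                study.cine.contours[p_lge][s][which], config.landmarks_per_contour,
                mode=config.landmark_mode))
        per_slice.append(fit_bspline(
            np.vstack(src_pts), np.vstack(dst_pts),
            grid_spacing=config.bspline_grid_spacing,
            regularization=config.bspline_regularization,
        ))
    xfm = stack_transforms(per_slice)
    lge_reg = apply_transform(study.lge, xfm)

    myo_dwi = study.true_myocardium
    lge_geom = study.lge
    myo_lge_full = contours_to_myocardium_mask(b0_contours, lge_geom)
    myo_lge = _erode_endocardial_ring(myo_lge_full, b0_contours, lge_geom)

    labels_dwi = assign_segments_stack(myo_dwi, study.b0, cfg.reference_angle_deg)
    labels_lge = assign_segments_stack(myo_lge, lge_geom, cfg.reference_angle_deg)

    rwm = chord_displacement(study.cine, reference_phase=0, n=config.n_chords)
    chord_labels = np.stack([
        segment_for_angles(level, rwm.angles_deg - cfg.reference_angle_deg)
        for level in ("basal", "mid", "apical")
    ])

    return SubjectWorkspace(
        study=study,
        adc=adc,
        lge_registered=lge_reg,
        myo_dwi=myo_dwi,
        myo_lge=myo_lge,
        labels_dwi=labels_dwi,
        labels_lge=labels_lge,
        rwm=rwm,
        chord_labels=chord_labels,
        matched_b0_phase=p_b0,
        matched_lge_phase=p_lge,
        registration_rmse_mm=xfm.meta.get("residual_rmse_mm", []),
    )


def _sector_mask(reference: ImageStack, myo: np.ndarray, center_deg: float, width_deg: float,
                 reference_angle_deg: float, slice_index: int = 0) -> np.ndarray:
    _, theta = reference.polar_grid(reference_angle_deg)
    mask = np.zeros_like(myo)
    mask[slice_index] = myo[slice_index] & (angle_difference(theta, center_deg) <= width_deg / 2.0)
    return mask


def _auto_seeds(data: np.ndarray, myo: np.ndarray, detect_cutoff: float) -> list[tuple[int, int, int]]:
    """One seed per slice with detectable hyperintensity: the in-myocardium
    argmax of the median-filtered image (background zeroed first)."""
    seeds = []
    work = np.where(myo, data, 0.0)
    for s in range(data.shape[0]):
        filt = ndimage.median_filter(work[s], size=3)
        filt[~myo[s]] = -np.inf
        if np.nanmax(np.where(myo[s], data[s], -np.inf)) <= detect_cutoff:
            continue
        r, c = np.unravel_index(np.argmax(filt), filt.shape)
        seeds.append((s, int(r), int(c)))
    return seeds


def _jitter_seeds(seeds, myo, rng, jitter_px: int, data: np.ndarray | None = None,
                  min_brightness_fraction: float = 0.8):
    """Perturb seed voxels the way a reviewer would: within the myocardium
    and only onto voxels that still look bright (median-filtered intensity
    within ``min_brightness_fraction`` of the unperturbed seed's) — a human
    places the kernel in the visibly hyperintense core, not on its rim."""
    filt = None
    if data is not None:
        filt = np.stack([ndimage.median_filter(np.where(myo[s], data[s], 0.0), size=3)
                         for s in range(data.shape[0])])
    out = []
    for s, r, c in seeds:
        placed = False
        for _ in range(50):
            rr = r + rng.integers(-jitter_px, jitter_px + 1)
            cc = c + rng.integers(-jitter_px, jitter_px + 1)
            if not myo[s, rr, cc]:
                continue
            if filt is not None and filt[s, rr, cc] < min_brightness_fraction * filt[s, r, c]:
                continue
            if data is not None:
                # the reviewer clicks the locally hottest voxel around the
                # perturbed position, never a dim rim voxel
                rr, cc = _snap_to_local_max(data[s], myo[s], rr, cc)
            out.append((s, int(rr), int(cc)))
            placed = True
            break
        if not placed:
            warnings.warn("seed perturbation left the bright core; keeping the unperturbed seed")
            out.append((s, r, c))
    return out


def _snap_to_local_max(data2d: np.ndarray, myo2d: np.ndarray, r: int, c: int) -> tuple[int, int]:
    r0, r1 = max(r - 1, 0), min(r + 2, data2d.shape[0])
    c0, c1 = max(c - 1, 0), min(c + 2, data2d.shape[1])
    window = np.where(myo2d[r0:r1, c0:c1], data2d[r0:r1, c0:c1], -np.inf)
    dr, dc = np.unravel_index(np.argmax(window), window.shape)
    return r0 + int(dr), c0 + int(dc)


def _classify_modality(data_stack, myo, roi, seeds, config: StudyConfig):
    thr = threshold_classify(data_stack, roi, myo, n_sd=config.threshold_n_sd)
    if seeds:
        fw = fwhm_classify(data_stack, seeds, myo, fraction=config.fwhm_fraction)
    else:
        fw = InfarctMask(np.zeros_like(myo), "fwhm", myo, provenance={"seeds": []})
    return thr, fw


def reviewer_pass(ws: SubjectWorkspace, config: StudyConfig, rng, reviewer: str) -> dict:
    """One reviewer's analysis of one subject (seeded ROI/seed perturbations)."""
    cfg = ws.study.config
    roi_center = config.remote_roi_center_deg + rng.uniform(
        -config.roi_center_jitter_deg, config.roi_center_jitter_deg)

    roi_dwi = _sector_mask(ws.study.b0, ws.myo_dwi, roi_center,
                           config.remote_roi_width_deg, cfg.reference_angle_deg)
    roi_lge = _sector_mask(ws.study.lge, ws.myo_lge, roi_center,
                           config.remote_roi_width_deg, cfg.reference_angle_deg)

    adc_roi_vals = ws.adc.data[roi_dwi]
    adc_cutoff = adc_roi_vals.mean() + config.threshold_n_sd * adc_roi_vals.std(ddof=1)
    lge_roi_vals = ws.lge_registered.data[roi_lge]
    lge_cutoff = lge_roi_vals.mean() + config.threshold_n_sd * lge_roi_vals.std(ddof=1)

    adc_seeds = _jitter_seeds(_auto_seeds(ws.adc.data, ws.myo_dwi, adc_cutoff),
                              ws.myo_dwi, rng, config.seed_jitter_px, data=ws.adc.data)
    lge_seeds = _jitter_seeds(_auto_seeds(ws.lge_registered.data, ws.myo_lge, lge_cutoff),
                              ws.myo_lge, rng, config.seed_jitter_px,
                              data=ws.lge_registered.data)

    adc_thr, adc_fw = _classify_modality(ws.adc, ws.myo_dwi, roi_dwi, adc_seeds, config)
    lge_thr, lge_fw = _classify_modality(ws.lge_registered, ws.myo_lge, roi_lge, lge_seeds, config)

    masks = {("adc", "threshold"): adc_thr, ("adc", "fwhm"): adc_fw,
             ("lge", "threshold"): lge_thr, ("lge", "fwhm"): lge_fw}

    out: dict = {"reviewer": reviewer, "roi_center_deg": float(np.mod(roi_center, 360.0))}
    contours_b0 = ws.study.contours(cfg.dwi_phase)
    for (modality, method), mask in masks.items():
        labels = ws.labels_dwi if modality == "adc" else ws.labels_lge
        ref = ws.study.b0 if modality == "adc" else ws.study.lge
        key = f"{modality}_{method}"
        out[f"volume_{key}"] = infarct_volume_pct(mask)
        out[f"score_{key}"] = score_segments(mask, labels, modality=modality, reviewer=reviewer)
        # qualitative assessment: close single-voxel noise holes first; the
        # LGE wall is analyzed minus the endocardial ring, allowed for in the
        # coverage tolerance; speck components are not assessed as infarcts
        closed = np.stack([
            ndimage.binary_closing(sl, structure=ndimage.generate_binary_structure(2, 1))
            for sl in mask.mask
        ]) & (ws.myo_dwi if modality == "adc" else ws.myo_lge)
        tm = transmurality(closed, contours_b0, ref,
                           tolerance_px=3.0 if modality == "lge" else 2.0,
                           min_component_voxels=5)
        out[f"transmural_{key}"] = bool(tm and all(tm))
        out[f"dice_{key}"] = _dice(mask.mask, ws.study.true_infarct if modality == "adc"
                                   else ws.study.lge_true_infarct & ws.myo_lge)

    # regional ADC
    out["adc_remote"] = float(adc_roi_vals.mean())
    for method in ("threshold", "fwhm"):
        m = masks[("adc", method)].mask
        out[f"adc_infarct_{method}"] = (
            float(mean_region_adc(ws.adc, m)[0]) if m.any() else float("nan"))

    # regional wall motion averaged over chords containing the ADC infarct
    r_grid, theta_grid = ws.study.b0.polar_grid(cfg.reference_angle_deg)
    chord_width = 360.0 / config.n_chords
    for method in ("threshold", "fwhm"):
        m = masks[("adc", method)].mask
        vals = []
        for s in range(m.shape[0]):
            if not m[s].any():
                continue
            bins = np.unique(np.minimum(
                (theta_grid[m[s]] / chord_width).astype(int), config.n_chords - 1))
            vals.extend(ws.rwm.displacement[s, bins])
        out[f"rwm_infarct_{method}"] = float(np.mean(vals)) if vals else float("nan")
    roi_bins = np.unique(np.minimum(
        (theta_grid[roi_dwi[0]] / chord_width).astype(int), config.n_chords - 1))
    out["rwm_remote"] = float(np.mean(ws.rwm.displacement[0, roi_bins]))

    out["akinesis_score"] = classify_akinetic(ws.rwm, ws.chord_labels,
                                              cutoff_mm=config.akinesis_cutoff_mm)
    return out


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else float("nan")


# ------------------------------------------------------------------ the study


def simulate_reviewers(config: StudyConfig, workspaces: list) -> dict:
    """Two blinded reviewers plus one repeat by reviewer 1, all seeded."""
    passes = {}
    for tag, stream in (("reviewer1", 10), ("reviewer2", 11), ("reviewer1_repeat", 12)):
        rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, stream]))
        passes[tag] = [reviewer_pass(ws, config, rng, tag) for ws in workspaces]
    return passes


def _volume_agreement(x, y) -> dict:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bias, loa = ag.bland_altman(x, y)
    rep = {
        "icc": ag.icc(x, y),
        "r_squared": ag.pearson_r2(x, y),
        "bias": bias,
        "loa": list(loa),
    }
    try:
        rep["wilcoxon_p"] = ag.wilcoxon_signed_rank(x, y).p_value
    except ValueError:
        rep["wilcoxon_p"] = None
    return rep


def _location_agreement(test_scores, gold_scores, alpha: float) -> dict:
    t = ag.contingency(test_scores, gold_scores, "ADC", "LGE")
    rep = {
        "table": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
        "n_segments": t.total,
        "segments_in_agreement": t.a + t.d,
        "percent_agreement": ag.percent_agreement(t),
        "kappa": ag.cohens_kappa(t),
        "n_gold_positive": t.a + t.c,
        "n_test_positive": t.a + t.b,
        **ag.diagnostic_metrics(t),
    }
    try:
        w = ag.wilcoxon_signed_rank(ag._flatten_scores(test_scores),
                                    ag._flatten_scores(gold_scores), alpha=alpha)
        rep["wilcoxon_p"] = w.p_value
        rep["significant"] = w.significant
    except ValueError:
        rep["wilcoxon_p"] = None
        rep["significant"] = False
    return rep


def run_study(config: StudyConfig) -> dict:
    """Full study replica; deterministic for a fixed master seed."""
    cohort = sample_cohort(config)
    studies = [generate_phantom(c) for c in cohort]
    workspaces = [prepare_subject(s, config) for s in studies]
    passes = simulate_reviewers(config, workspaces)
    r1 = passes["reviewer1"]

    report: dict = {"config": {"cohort_size": config.cohort_size, "master_seed": config.master_seed}}

    # ---- Table-1-like: regional means ± SD (reviewer 1)
    def _ms(key):
        vals = np.array([p[key] for p in r1], dtype=float)
        vals = vals[~np.isnan(vals)]
        return {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}

    table1 = {
        "adc_remote": _ms("adc_remote"),
        "adc_infarct_fwhm": _ms("adc_infarct_fwhm"),
        "adc_infarct_threshold": _ms("adc_infarct_threshold"),
        "rwm_remote": _ms("rwm_remote"),
        "rwm_infarct_fwhm": _ms("rwm_infarct_fwhm"),
        "rwm_infarct_threshold": _ms("rwm_infarct_threshold"),
    }
    for method in ("fwhm", "threshold"):
        try:
            table1[f"wilcoxon_p_adc_{method}"] = ag.wilcoxon_signed_rank(
                [p[f"adc_infarct_{method}"] for p in r1],
                [p["adc_remote"] for p in r1]).p_value
            table1[f"wilcoxon_p_rwm_{method}"] = ag.wilcoxon_signed_rank(
                [p[f"rwm_infarct_{method}"] for p in r1],
                [p["rwm_remote"] for p in r1]).p_value
        except ValueError:
            table1[f"wilcoxon_p_adc_{method}"] = None
            table1[f"wilcoxon_p_rwm_{method}"] = None
    report["table1"] = table1

    # ---- Table-2-like: infarct volumes and their agreement
    table2 = {}
    for method in ("fwhm", "threshold"):
        adc_v = [p[f"volume_adc_{method}"] for p in r1]
        lge_v = [p[f"volume_lge_{method}"] for p in r1]
        table2[method] = {
            "adc_volume": _ms(f"volume_adc_{method}"),
            "lge_volume": _ms(f"volume_lge_{method}"),
            "adc_vs_lge": _volume_agreement(adc_v, lge_v),
            "interobserver_adc": _volume_agreement(
                adc_v, [p[f"volume_adc_{method}"] for p in passes["reviewer2"]]),
            "interobserver_lge": _volume_agreement(
                lge_v, [p[f"volume_lge_{method}"] for p in passes["reviewer2"]]),
            "intraobserver_adc": _volume_agreement(
                adc_v, [p[f"volume_adc_{method}"] for p in passes["reviewer1_repeat"]]),
            "intraobserver_lge": _volume_agreement(
                lge_v, [p[f"volume_lge_{method}"] for p in passes["reviewer1_repeat"]]),
        }
    report["table2"] = table2

    # ---- Table-3-like: segment location agreement (ADC vs LGE gold standard)
    alpha = ag.bonferroni_alpha()
    table3 = {}
    for method in ("fwhm", "threshold"):
        table3[method] = {
            rev: _location_agreement(
                [p[f"score_adc_{method}"] for p in passes[rev]],
                [p[f"score_lge_{method}"] for p in passes[rev]],
                alpha,
            )
            for rev in ("reviewer1", "reviewer2")
        }
        table3[method]["interobserver_adc_kappa"] = ag.cohens_kappa(ag.contingency(
            [p[f"score_adc_{method}"] for p in r1],
            [p[f"score_adc_{method}"] for p in passes["reviewer2"]]))
        table3[method]["interobserver_lge_kappa"] = ag.cohens_kappa(ag.contingency(
            [p[f"score_lge_{method}"] for p in r1],
            [p[f"score_lge_{method}"] for p in passes["reviewer2"]]))
    report["table3"] = table3

    # ---- wall motion and transmurality summaries
    akinetic_total = int(sum(p["akinesis_score"].values.sum() for p in r1))
    encaps = []
    for p in r1:
        ak = p["akinesis_score"].values
        for method in ("fwhm", "threshold"):
            for modality in ("adc", "lge"):
                sc = p[f"score_{modality}_{method}"].values
                encaps.append(bool(np.all(ak >= sc)))
    report["wall_motion"] = {
        "n_akinetic_segments": akinetic_total,
        "akinesis_encapsulates_infarct": bool(all(encaps)),
        "encapsulation_rate": float(np.mean(encaps)),
    }
    report["transmurality"] = {
        f"{modality}_{method}": [bool(p[f"transmural_{modality}_{method}"]) for p in r1]
        for modality in ("adc", "lge") for method in ("fwhm", "threshold")
    }

    # ---- ground truth columns
    report["ground_truth"] = {
        "true_infarct_fraction_pct": [float(s.meta["infarct_fraction_pct"]) for s in studies],
        "true_remote_adc": [float(s.config.remote_adc) for s in studies],
        "true_infarct_adc": [float(s.config.infarct_adc) for s in studies],
        "matched_b0_phase_correct": [
            ws.matched_b0_phase == ws.study.config.dwi_phase for ws in workspaces],
        "matched_lge_phase_correct": [
            ws.matched_lge_phase == ws.study.config.lge_phase for ws in workspaces],
        "mean_dice_adc_fwhm": float(np.mean([p["dice_adc_fwhm"] for p in r1])),
        "volume_error_adc_fwhm_pp": [
            float(p["volume_adc_fwhm"] - s.meta["infarct_fraction_pct"])
            for p, s in zip(r1, studies)],
    }
    report["_passes"] = passes
    report["_workspaces"] = workspaces
    return report


def _strip_private(obj):
    if isinstance(obj, dict):
        return {k: _strip_private(v) for k, v in obj.items() if not str(k).startswith("_")}
    if isinstance(obj, (list, tuple)):
        return [_strip_private(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_report(report: dict, outdir) -> None:
    """Serialize the study report: summary JSON plus per-table CSVs."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "summary.json", "w") as fh:
        json.dump({"schema_version": 1, **_strip_private(report)}, fh, indent=2, default=str)
    rows = []
    for rev, passes in report["_passes"].items():
        for i, p in enumerate(passes):
            row = {"subject": i, "reviewer": rev}
            for k, v in p.items():
                if k.startswith(("volume_", "adc_", "rwm_", "dice_", "transmural_")):
                    row[k] = v
                if k.startswith("score_") or k == "akinesis_score":
                    row[k] = "".join(map(str, v.values))
            rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "subjects.csv", index=False)
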