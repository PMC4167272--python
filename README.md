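# dwcmr — contrast-free chronic infarct characterization with diffusion-weighted cardiac MR

Late gadolinium enhancement (LGE) is the clinical gold standard for sizing
and locating chronic myocardial infarction, but gadolinium is
contraindicated in many patients with renal disease.  Diffusion-weighted
cardiac MR (dwCMR) offers a contrast-free alternative: chronic infarcts are
fibrotic, water diffuses faster in fibrotic tissue, and the apparent
diffusion coefficient (ADC) rises by roughly 70% over remote myocardium.
`dwcmr` is a tested, reusable implementation of the complete analysis chain
that turns a 3-slice short-axis acquisition into an infarct
characterization and a head-to-head statistical comparison against LGE —
driven by a fully ground-truthed digital left-ventricular phantom, so every
stage can be validated without animal data.

It is aimed at cardiac-MR methods researchers who want a reference
implementation of the standard infarct-quantification toolbox (semi-automatic
classifiers, AHA scoring, chord-based wall motion, agreement statistics) and
a controllable phantom to stress it with.

## What it computes

**ADC mapping.**  Per-direction maps from the two-point monoexponential fit
`ADC = ln(S0/Sb)/b` at b = 400 s/mm², combined into the trace map
`ADC = (ADC_x + ADC_y + ADC_z)/3` (units μm²/ms; 1 μm²/ms = 10⁻³ mm²/s).

**Diffusion preparation verification.**  Exact (closed-form) gradient
moments `M_n = ∫ G_eff(t) tⁿ dt` and b-value `b = γ² ∫ (∫₀ᵗ G_eff)² dt` for
piecewise-trapezoidal waveforms with refocusing-pulse polarity inversion,
plus a designer for a quadra-lobed waveform with `M0 = M1 = M2 = 0`
(first- and second-order motion compensation) that hits a b-value target
under maximum-gradient and preparation-window constraints.

**Infarct quantification.**  Two standard semi-automatic classifiers applied
identically to ADC maps and co-registered LGE: the n-SD threshold
(infarct = voxels above remote mean + 6 SD) and the two-stage
full-width-half-maximum (FWHM) region-growing criterion.  Volumes are
percentages of the 3-slice LV myocardium; transmurality is scored per
infarct.

**Co-registration.**  The two-step scheme: the cine phases matching the b0
and LGE acquisitions are identified, a non-rigid cubic B-spline point-based
registration is estimated between those cine frames from endo/epicardial
landmarks, and that transform — never one fitted to the ADC/LGE images
themselves — is applied to the LGE image.

**Wall motion.**  100 evenly spaced chords per slice from a fixed LV
centre; regional wall motion (RWM) is the maximal endocardial excursion
along each chord over 35 cardiac phases; segments with mean |displacement|
≤ 3 mm are akinetic.

**AHA scoring and agreement.**  16-segment model (6 basal + 6 mid + 4
apical), any-voxel positivity, pooled across subjects; Cohen's κ,
sensitivity/specificity/PPV/NPV against LGE as gold standard, Bland–Altman
bias and limits of agreement, ICC(2,1), Pearson R², and Wilcoxon
signed-rank tests with Bonferroni control (p < 0.0045 for the location
battery).

**Phantom.**  A seeded digital LV: three 6-mm short-axis slices (base, mid,
apex) with a transmural anteroseptal infarct (~11% of the imaged LV),
remote/infarct trace ADC 1.4/2.4 μm²/ms, remote/infarct endocardial
excursion 8.3/0.9 mm, DWI at 2.1 mm, LGE at 1.3 mm (generated in a
different cardiac phase, so registration has real work), cine at 1.4 mm
over 35 phases, and Rician noise at a configurable SNR.  Ground truth (ADC
map, masks, motion model, inter-phase warp) is carried with the images.

## Worked example

Run the full study replica — an 11-subject phantom cohort, two simulated
reviewers plus a repeat — and print the headline numbers:

```bash
$ dwcmr run --out results/demo --seed 1
remote ADC 1.40 ± 0.01 μm²/ms; infarct (FWHM) 2.41 ± 0.02 μm²/ms
ADC-vs-LGE segment kappa (FWHM, reviewer 1): 1.000
report written to results/demo
```

The remote myocardium reads 1.40 μm²/ms and the FWHM-delineated infarct
2.41 μm²/ms — the configured tissue values (1.4 and 2.4), recovered through
the noisy forward model, i.e. a ~70% ADC elevation.  κ = 1.0 means the ADC-
and LGE-derived AHA segment scores agreed on all 176 pooled segments of
this cohort.  `results/demo/summary.json` holds the full report (regional
means, volume ICC/R²/bias, contingency tables, reviewer reproducibility,
akinesis and transmurality), and `results/demo/subjects.csv` the
per-subject values.

Verify the diffusion preparation at the protocol constraints
(b = 400 s/mm², G_max = 43 mT/m, TE_prep = 105 ms):

```bash
$ dwcmr prep-design --b 400 --gmax 43 --teprep 105
{
  "b_value_s_per_mm2": 400.0000411575426,
  "moments": {"M0": -5.1e-12, "M1": 3.9e-10, "M2": -1.1e-08},
  "duration_ms": 87.28828239440918,
  "max_amplitude_mT_per_m": 43.0
}
```

The returned waveform nulls M0, M1 and M2 to numerical precision and
reaches the target b-value inside the 105 ms window.  A single phantom
subject can be written to NIfTI with `dwcmr simulate --out subj0/ --seed 0`.

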