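# Methods

This note records the models implemented in `dwcmr`, the parameters that
matter, the design decisions taken where the design was genuinely open, and
what the synthetic phantom does and does not establish about real data.

## Signal model and ADC estimation

Diffusion-weighted magnitude images follow the monoexponential forward
model `S_b = S0 · exp(−b · ADC)` per voxel, with b in s/mm² and ADC stored
in μm²/ms (1 μm²/ms = 10⁻³ mm²/s; the factor is applied once, at fit
time).  The two-point estimator `ADC = ln(S0/S_b)/b` is exact for
noise-free data.  Voxels where either signal is non-positive have no
defined fit and are flagged invalid and excluded from regional means —
clamping negative fits to zero would bias those means, which is the
quantity the analysis reports.  Negative ADC values arising from noise
(`S_b > S0`) are retained as valid for the same reason.  The trace map is
the voxelwise mean of the three orthogonal directional maps, with validity
the intersection of the inputs.

At the default phantom SNR (see below) the per-voxel trace-ADC noise SD is
≈ 0.07 μm²/ms, so regional means over hundreds of voxels recover the
tissue values to well under 1%.  The Rician floor biases the b-400 signal
upward by σ²/2S, a relative ADC bias below 0.5% at the default SNR; the
test suite characterizes this by sweeping SNR and checking convergence to
truth rather than hiding it.

## Diffusion-preparation design

Gradient moments `M_n = ∫ G_eff(t) tⁿ dt` and the b-value
`b = γ² ∫ q(t)² dt`, `q(t) = ∫₀ᵗ G_eff`, are evaluated in closed form over
the piecewise-linear effective gradient (polynomial integration per
trapezoid segment), so the only numerical error is float rounding.
Refocusing pulses are polarity markers: every segment after a marker has
its sign flipped once per preceding marker.  RF pulse shapes,
eddy-currents and slew-rate optimization are out of scope.

The moment-nulled designer uses four identical, contiguous, equally spaced
trapezoids with amplitudes in the ratio (1, −3, 3, −1)/3 scaled to the
gradient limit.  Third-difference weights annihilate every polynomial of
degree ≤ 2 in the lobe offset, so M0, M1 and M2 vanish exactly for any
lobe shape — no numerical nulling is needed.  The single free parameter,
the common flat-top duration, is found by monotone bisection on the
exactly computed b-value (tolerance 10⁻⁶ relative); the longest waveform
fitting the preparation window bounds the achievable b, and an infeasible
target raises an error stating that bound.  At the protocol constraints
(43 mT/m, 105 ms window, 0.5 ms ramps) the scheme reaches b = 400 s/mm²
with ≈ 17 ms to spare.

## The digital LV phantom

Each slice is an annulus; the myocardium between the endo- and epicardial
radii, blood inside, air outside, rasterized by centre-of-voxel inclusion.
Defaults emulate a 3-slice short-axis porcine protocol: 6 mm slices,
end-diastolic endo/epi radii (17/28, 15/26, 11/22) mm for base/mid/apex,
DWI at 2.1 mm on a 64² grid, LGE at 1.3 mm on 104², cine at 1.4 mm on 96²
over 35 phases.  S0 is 100 in myocardium and 120 in blood; LGE intensities
are 15 (remote, nulled), 90 (infarct), 45 (blood).

**Infarct.**  A transmural anteroseptal wedge (default centre 50°, CCW
from the anterior reference ray) spanning all three slices; its angular
extent is solved by root-finding so that the infarct occupies a requested
percentage of the imaged LV volume *at the acquisition phase* (default
≈ 11%).  Infarct ADC follows a smooth unimodal angular profile,
`ADC(u) = μ + A·((1−u²)² − mean)` with u the normalized angular offset,
mean-centred per realization so the spatial mean is exactly the configured
μ = 2.4 μm²/ms (peak ≈ 3.06, rim ≈ 1.66 at the default amplitude
A = 1.4).  A flat profile would be incompatible with the FWHM criterion on
ADC maps — half of 2.4 is below the 1.4 remote level and the region grower
would flood the myocardium — whereas chronic infarcts have hot cores.  The
default amplitude places the half-of-peak level midway between the rim and
remote myocardium, which maximizes the margin of the two-stage rule on
both sides; it is a property the real data must also have had for the
criterion to work there.

**Motion.**  Radial contraction `r(θ, φ) = r_ED(θ) − e(θ)·m(φ)` with
`m(φ) = sin²(πφ/(P−1))` (phase 0 = end-diastole, maximal cavity).  The
peak endocardial excursion e is 8.3 mm in remote wall and 0.9 mm in the
infarct, with the hypokinetic zone extending 55° beyond the infarct edges
and a 20° smooth transition; the epicardium moves at 35% of the
endocardial excursion (wall thickening).  The 55° margin is the analytic
minimum for which the segment-mean akinesis rule (≤ 3 mm) covers any
infarct sliver of ≥ 6° in a 90° apical segment, i.e. it guarantees by
construction the physiological fact that the hypokinetic territory
encloses the infarct; it also produces roughly half of all segments
akinetic, as in chronically infarcted animals.  A 20° border zone is
physiologically graded and, not incidentally, resolvable by a B-spline at
clinical control-point spacing — a 10° transition produced local
registration residuals that leaked blood signal into the subendocardial
LGE ring.

**LGE geometry.**  The LGE image is rendered in a different cardiac phase
(default 10 vs 27 for DWI), so the registration stage has a known
non-trivial warp to recover: material points keep their angle and
normalized transmural depth between phases, which defines the ground-truth
transform used to score registration.

**Noise.**  Magnitude-MR (Rician): `out = |signal + complex Gaussian|`,
σ = reference amplitude / SNR, with the reference the remote-myocardium b0
signal (DWI), the infarct level (LGE), or the myocardial cine intensity.
The source protocol states no noise figures; the default SNR of 50 was
chosen so that the 6-SD threshold remains meaningful on ADC maps (the
per-voxel ADC noise SD must stay below (2.4−1.4)/6 ≈ 0.17 μm²/ms with
margin), and tests sweep SNR rather than treating 50 as a truth claim.

**What the phantom does not emulate:** partial-volume averaging at tissue
interfaces, B1 and coil shading, readout artifacts and distortions,
through-plane motion, papillary muscles, realistic torso anatomy, and
intensity textures within tissue classes.  Passing tests therefore show
that the *analysis chain* is correct and robust to Rician noise and
operator perturbation under the stated geometry — not that it would be
robust to every artifact of in vivo acquisition.

## Classifiers

Both classifiers are restricted to a myocardium mask and share one code
path for ADC and LGE inputs.  The threshold rule classifies voxels
strictly above `mean + 6·SD` of a manually placed remote ROI
(sample SD; a zero-SD ROI degenerates to a cutoff at the mean; a
single-voxel ROI is an error).  The FWHM rule is two-stage: a seed region
grown from a seed voxel over connected voxels ≥ 50% of the *seed*
intensity, then a final mask of myocardial voxels ≥ 50% of the seed
region's *maximum*, restricted to connected components touching the seed
region.  Connectivity is 4-neighbour in-plane with no through-plane
growth (slices are 6 mm apart); multi-slice infarcts take one seed per
slice.  The component restriction resolves an ambiguity in the textual
rule (global vs region-restricted thresholding) in favour of not
harvesting remote false positives.

On this phantom the 6-SD threshold systematically under-reads ADC volumes
by ≈ 2 percentage points: the cutoff (≈ remote + 0.4 μm²/ms under noise)
sits above the infarct rim of the unimodal profile.  The FWHM rule does
not, because the rim stays above half-of-peak by construction.  This
mirrors the field's experience that FWHM sizes infarcts more accurately.

## Registration

Per-slice 2-D cubic B-spline displacement fields in physical coordinates,
fitted to corresponding endo/epicardial landmark points by least squares
with a bending-energy penalty (squared second differences of the control
displacements; weight 10⁻³, control spacing 10 mm by default).  With zero
regularization the minimum-norm exact interpolant is used.  The stored
displacement is the backward map (`output(x) = image(x + u(x))`), so the
transform applied to LGE is fitted from b0-phase landmarks to LGE-phase
landmarks.  Landmarks are sampled at equal polar angle from the LV centre
(50 per contour): under radial motion equal-angle points are exactly
corresponding material points, whereas equal arc-length sampling (provided
as an option) introduces a correspondence error that is not a property of
the registration; the original method's landmark choice is not public, so
this is a package decision, not a claim about it.  Phase matching is
automated as the argmin of mean symmetric contour distance (or normalized
intensity difference when only images are available), ties broken toward
the earlier phase — a surrogate for the visual screening a human does.

The transform is always estimated between cine frames and applied to LGE;
estimating it on the ADC/LGE pair directly could absorb genuine
delineation differences into the warp.

## Pipeline conventions

The study replica runs, per subject: ADC fit → phase match → registration
→ classifiers on both modalities → volumes → AHA scores, wall motion and
transmurality → pooled statistics; everything derives from one master
seed.  Decisions a human operator makes are replicated as seeded
perturbation models: the remote ROI (lateral wall of the most basal slice,
60° sector) is jittered ±10° in position, and FWHM seeds are jittered by
one pixel and then snapped to the locally hottest voxel in a 3×3
neighbourhood — a reviewer places the kernel on the visibly hyperintense
core, never a dim rim voxel, and modelling that stabilizes the seed-region
maximum exactly as intended by the two-stage rule.

Two resampling artifacts are handled explicitly.  (1) The co-registered
LGE is analyzed inside a myocardium mask eroded by two pixels at the
endocardial border: backward-warp interpolation at the blood interface
manufactures intermediate intensities that a noise-free 6-SD threshold
would misread as enhancement.  Both the numerator and denominator of the
LGE volume use the eroded wall, so the percentage stays unbiased.  (2) The
cohort sampler keeps infarct wedge edges ≥ 12° away from AHA sector
boundaries: the any-voxel segment rule makes sub-voxel slivers (one DWI
voxel subtends ≈ 6° at the outer wall) grid-dependent, which is an
artifact of discretization, not of either modality.

Transmurality is assessed qualitatively, as a reader would: masks are
binary-closed (single-voxel noise holes), speck components under 5 voxels
are not treated as infarcts, rays within two voxel-widths of the angular
span edges are excluded, and wall coverage must run endo-to-epi within a
small pixel tolerance (2 px on the DWI grid, 3 px on the endo-eroded LGE
grid) with at most a one-voxel radial gap.  A half-thickness
subendocardial wedge is still classified non-transmural at these settings.

Statistics: Cohen's κ, percent agreement and the diagnostic metrics use
their standard closed forms on the pooled 2×2 table (metrics with a zero
marginal are reported as NaN, not 0).  ICC is the two-way random-effects,
absolute-agreement, single-measure form ICC(2,1), the usual choice within
the Shrout–Fleiss framework when the specific form is not named, computed
via pingouin and cross-checked in the tests against a two-way ANOVA
implementation.  The Wilcoxon signed-rank test drops zero differences,
uses the exact sign-assignment distribution for n ≤ 25 (computed by
convolution over doubled midranks, valid under ties) and the tie-corrected
normal approximation above; Bonferroni control for the segment-location
battery divides α = 0.05 by 11 comparisons (0.0045).  Bland–Altman
differences are ADC − LGE throughout.

## Cohort design

Eleven subjects per study.  True infarct fractions are drawn from
N(11%, 3.5%) clipped to [4, 18]%, the wedge centre from N(50°, 6°)
(rejection-sampled for the boundary margin), and the whole-heart scale
jittered by 3%; the tissue ADC means are the group values (1.4 and
2.4 μm²/ms) for every subject, so the cohort varies anatomy, lesion size
and noise realization rather than biology that the source conditions fix
as single group means.  Reviewer replicas differ only in their seeded
perturbations; "reviewer 1 repeat" is an independent draw from the same
perturbation model.

## Known limitations

* The phantom's motion is purely radial and in-plane; chord displacement
  and the registration ground truth inherit that simplification.
* The FWHM stage-1 rule is intrinsically fragile on ADC maps whenever half
  the seed intensity approaches the remote level; the implementation is
  faithful to the two-stage rule, and the pipeline's seed model (hottest
  local voxel) is what keeps it stable — as it is in practice.
* Segment scores are pooled across subjects in all κ computations; no
  within-subject correlation correction is applied.
* The 17th (apex-cap) segment is not acquired in a 3-slice protocol and is
  never scored.
* Volumes come from three slices, not whole-heart coverage; percentages
  are relative to the imaged myocardium only.
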