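# Methods

## Forward model of the synthetic cohort

Each subject is a single 2-D axial slice rendered over time. The acquisition
follows the default protocol: contrast injection of 80 ml at 5.0 ml/s
starting at t = 0, and 34 frames every 1.5 s beginning 13 s after injection
start. All times in the package are absolute seconds on this axis.

**Arterial input function.** The aortic curve is a gamma variate,

    AIF(t) = b + A·(t − t0)^α · exp(−(t − t0)/β)   for t > t0,  else b,

with baseline b = 50 HU, onset t0 = 11 s, shape α = 4, scale β = 3 by
default, and the amplitude parameterised through the peak enhancement
(default 250 HU; `AifParams.from_peak`). The peak falls at t0 + αβ = 23 s,
and the absolute 120 HU bolus-tracking trigger fires at the third frame
(16 s) — two to three frames into the window, as a clinical bolus-tracking
setup would aim for. **The 250 HU peak default and the 50 HU baseline are
coupled to the 120 HU trigger: change one and you should revisit the
others** (a peak below the trigger makes the subject invalid and is
rejected).

**Tissue curves.** Tissue kinetics follow the first-pass indicator-dilution
form with a boxcar residue R(lag) = 1 for lag < MTT, else 0:

    TAC(t) = baseline_hu + (BF/6000) · ∫₀ᵗ AIF_enh(τ)·R(t − τ) dτ,

evaluated by cumulative trapezoidal integration on the acquisition grid
(the lagged term is linearly interpolated; lags before the first frame
contribute nothing, i.e. the grid is the measurement window). The factor
6000 converts (HU/s)/HU to ml/100 ml/min and is defined once
(`HU_RATE_TO_PERFUSION`).

**Default transit time = 28 s.** Both estimators assume no contrast leaves
the tissue before their last sample of interest. The swept second-scan
times extend to ~21.5 s after the trigger (~37.5 s absolute), so the
default MTT is set to 28 s — long enough that outflow begins only after the
last evaluated second scan and the no-outflow assumption holds across the
whole timing sweep. This is deliberately longer than a physiological
pancreatic transit time (~10 s): a hard boxcar cut-off at a short MTT
overstates outflow relative to real first-pass curves, whose dispersion and
recirculation keep tissue enhancement rising through this window. Shorter
MTTs are fully supported and are the intended way to probe how both
estimators degrade when the assumption is violated (late timings then
underestimate flow progressively).

**Cohort population.** Per-subject blood flow is drawn from truncated
normals matching reported patient statistics — parenchyma 106.8 ± 41.5,
carcinoma 42.0 ± 24.8 ml/100 ml/min, floored at 5 (rejection sampling) —
and the AIF onset (SD 1 s) and peak enhancement (SD 30 HU) are jittered
between subjects. A single seed drives everything; identical inputs give
bit-identical cohorts.

**Geometry and noise.** The default 128×128 slice (~1 mm pixels) holds an
aortic disk (145 px), polygonal carcinoma (679 px) and parenchyma
(2094 px) regions, and circular high-confidence ROIs strictly inside each
polygon (97 and 69 px) — the same order of magnitude as typical pancreatic
readings. Noise is additive i.i.d. Gaussian HU noise across voxels and
frames, default σ = 3 HU, representing the residual noise of a
motion-corrected, smoothly reconstructed dynamic series at the analysis
stage rather than raw low-dose projections. What the generator does *not*
emulate: breathing motion, beam hardening, spatially correlated noise,
intra-tissue flow heterogeneity, recirculation, and partial-volume mixing
at region borders. Passing tests therefore demonstrate correctness of the
estimators and pipeline plumbing under the stated model, not clinical
performance on patient data.

## Estimators

**Maximum slope.** The upslope is the maximum over all sliding windows
(default 3 consecutive frames) of the least-squares line slope of HU vs
time; BF = 6000·slope_max/(AIF_ref·ρ_t), with ρ_t = 1.0 g/ml by default so
flow is per tissue volume. AIF_ref is the maximum *enhancement* above
baseline by default; absolute-HU mode exists for sensitivity analysis. A
gamma-variate curve-fit slope estimator (`MSMConfig(estimator="gamma_fit")`)
is available for region-level curves, emulating curve-fitting
implementations; it is too slow to be the voxelwise default.

*Known limitation:* taking a per-voxel maximum of noisy window slopes is
biased upward (a max of noisy estimates), so voxelwise MSM means on noisy
data sit well above ground truth even though correlations — which ignore a
common shift — remain high. This is precisely why production MSM
implementations smooth or curve-fit the TACs first. ROI-level MSM (slope of
the ROI-mean TAC) or the curve-fit estimator avoid most of the bias.

**First-pass analysis.** ΔHU per voxel is the difference between the second
scan and the trigger-frame scan; the normaliser is the trapezoidal integral
of AIF enhancement between the same two frames. The voxelwise map is
6000·ΔHU/∫AIF_enh dt, whose compartment mean (compartment = union of the
polygonal tissue ROIs) equals the average perfusion identically; the raw
mean is stored in the map provenance and asserted in tests to 1e-9.
Negative voxels are floored to zero *after* that mean is recorded, and the
floored count is logged. The trigger comparison is strict (> 120 HU,
absolute), the first qualifying frame wins; AIF peak ties break to the
earliest frame; a second-scan target between frames takes the nearest
frame, the earlier one on ties; a target beyond the last frame raises a
window-exceeded error.

**Baselines.** Curve objects carry an explicit baseline. For extracted
curves the baseline is the mean of frames preceding the trigger (or the
first frame if none precede). Because the last pre-trigger frames already
enhance, this estimator is biased a few percent high; synthetic subjects
therefore carry their exact simulated AIF (`aif_true`, also written to
disk), which the pipeline prefers. On real data the bias propagates to a
comparable overestimate of flow and a dedicated pre-contrast baseline scan
would be preferable.

## Timing sweep

For each subject: one MSM map, one peak-timed FPA map (second scan at the
retrospective AIF maximum), and one FPA map per dispersion delay d
(default 0…13.5 s in 1.5 s steps, second scan nearest to
t_base + t_i/2 + d). Correlations against MSM pool both tissues: Pearson's
r over subject-level circular-ROI means (needs ≥ 3 points, i.e. ≥ 2
subjects; flagged degenerate otherwise) and over all polygonal-ROI voxels
concatenated across subjects. Per-tissue correlations are emitted for
diagnostics. The optimum range is the longest contiguous run of timings
with r strictly above both thresholds (0.90 means, 0.70 voxelwise);
`optimum_delay_window` maps its d-endpoints through t_p = t_i/2 + d to a
recommended second-scan delay window after the trigger.

COV across timings is computed per subject on the circular-ROI mean, then
averaged over subjects (primary), with the cohort-mean variant reported
alongside. Tissue contrast is an unpaired two-sided equal-variance t-test
on circular-ROI means at every timing (a paired mode exists); p-values are
reported raw, with no multiple-testing correction. Subjects whose trigger
never fires or whose second scan falls outside the window are skipped and
logged, never silently imputed.

## Dose accounting

Effective dose = DLP × k with k = 0.0153 mSv/(mGy·cm) for the abdomen. The
per-protocol DLP is a configuration input (no CT physics is modelled); the
two-scan DLP defaults to 2/34 of the dynamic DLP, i.e. dose scales with the
number of volumes, giving a ~94% reduction. Scan times follow the package's
own formulas — dynamic: (n_frames − 1)·cycle + exposure (50.0 s for the
default protocol); two-scan: monitoring lead + last-scan delay + exposure —
documented here because published scan-time figures often include
scanner-specific overheads that cannot be reconstructed from protocol
constants alone.

## Problem sizes and numerical choices

Default test and example workloads use the 128×128 slice, 34 frames and
16-subject cohorts (≈ 9 M voxel samples per cohort), which keeps a full
sweep under two seconds on one CPU; a 48×48 scaled geometry
(`PhantomGeometry.for_shape`) backs the smallest unit tests. Ties anywhere
(AIF peak, nearest frame) resolve to the earlier frame. Sample statistics
use ddof = 1. Truncated-normal draws use rejection sampling with a floor
fallback. The FPA normalisation identity is asserted at 1e-9;
noise-free parameter recovery at 5% (FPA is exact by construction there;
MSM is discretisation-limited to ~1–2% on the default grid).
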