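# Methods

This note documents the models, parameter choices and numerical
decisions behind `tonocore`, and what the synthetic validation does and
does not establish.

## Frequency scale

All tuning computations use the ERB-number ("Cam") scale,
`E(f) = a log10(b f + 1)` with `a = 21.4`, `b = 0.00437 /Hz`, and
`ERB_N(f) = 24.7 (4.37 f/kHz + 1)` Hz. One Cam step equals one normal
cochlear filter bandwidth, so tuning widths quoted in ERB_N are
standard deviations in Cam units. Constants are configurable on
`CochlearScale`. The 7-frequency stimulus construction (evenly spaced
in Cam between 251 and 6009 Hz) reproduces the published list to
within 2 Hz: this formula yields 507 and 2424 Hz where the published
list prints 505 and 2423; the interior anchor values 1501 and 3839 Hz
round exactly. Hz appears only at I/O boundaries.

## Synthetic cohort

The generator is the package's test bed: it emulates the *structure*
of flattened auditory-cortex data, not its physiology.

Geometry is built analytically in a gyrus frame (u along the HG long
axis, v across it; anterior = +v) and rotated into a 120×120 grid of
0.33-mm pixels (a ~40×40 mm patch — desk-scale runtime). Preferred
frequency follows

    pf(u, v) = cam_min + m_v(side) · fold(|v − v0|) + m_u · u

where `fold` reflects at the band width L = 9 mm. This yields a
low-frequency reversal line exactly on v = v0 (parallel to the HG
axis), high-frequency reversals at |v − v0| = L, and mirrored
low-frequency flanks beyond — so the orientation-counting detector
sees genuine sign changes of both denominations. The per-side
across-band slope m_v and the common along-axis tilt m_u realize the
configured gradient angles exactly (`atan2(±m_v, m_u)`, default ±70°);
sharing m_u between sides keeps the field continuous across the
reversal when the two angles are jittered independently.

The default across-band span is 9–23 Cam (~385 Hz–3.8 kHz), narrower
than the stimulus range: with the ±70° tilt over a 30-mm mask, a
stimulus-wide span would push the field far outside the audible range
the model bank covers, which no real map does. Straight reversal lines
(the real ones are curvilinear) keep truth analytic; the gradient-ROI
builder interpolates border positions along the axis, so curvilinear
reversals are handled too.

Other defaults, chosen once for realism at desk scale: Gaussian tuning
curves of height 1 (percent signal change) with width 9 ERB_N outside
and 4 ERB_N inside the high-selectivity ellipse; myelin baseline 0.70
with +0.05 inside the high-myelin ellipse; core ellipses 10–11 mm by
3.5–4 mm, parallel to the HG axis, slightly offset medially (myelin)
and laterally (selectivity); a Mexican-hat curvature ridge (amplitude
0.15, width 3 mm) whose crest carries the low-frequency reversal;
additive i.i.d. beta noise SD 0.3 (signal-to-noise ~3 at the mode,
before depth averaging) with emulated GLM residual variances
(chi-square with 44 dof) so F-tests behave as on real single-voxel
fits; per-hemisphere jitter of gradient angles (SD 8°), reversal
offset (SD 1 mm), HG-axis orientation (SD 5°) and effect sizes (10%).
Identical seeds give bit-identical cohorts.

The null-cohort switch replaces the V geometry by a *planar* gradient
pointing in an independent uniform random direction per hemisphere.
Rotating the V pattern instead would leave per-pixel direction
distributions bimodal-antipodal with unbalanced weights, for which the
Hotelling test is badly calibrated even though the true mean is zero;
a planar field gives i.i.d. uniform directions per pixel, the null the
type-I-error checks require.

What passing recovery tests show: the estimators are unbiased and
correctly wired on data whose generative model matches their
assumptions. What they do not show: robustness to BOLD hemodynamics,
pial-vein artifacts, flattening distortions, duplicated-gyrus
morphologies, or spatially correlated noise — none of which the
generator emulates.

## Response model

Sparse trial series (one acquisition per trial, TR 7.5 s) are
high-pass filtered per run with a discrete-cosine drift basis (0.01 Hz
cutoff; the constant is excluded so the mean survives), converted to
percent signal change about the run mean, concatenated, and fitted by
OLS with 7 stimulus-indicator regressors plus per-run intercepts
(whether the original analysis used per-run intercepts is unstated;
they are the conservative choice after concatenation and are flagged
in config). Silence is the baseline, so each beta is a
sound-versus-silence contrast. Responsive voxels come from the joint
F-test of all 7 betas with (7, dof) reference, FDR-corrected by the
two-stage adaptive step-up (plain BH by config flag) over the
candidate mask. The volumetric sphere-convolved candidate ROI of the
original workflow has no surface analogue here; the patch mask is the
candidate domain.

## Preferred frequencies and tuning widths

Centroid and spread use weights `max(β_i, 0)`. The spread is read as
the weighted standard deviation in Cam; the printed unweighted form is
retained behind `literal=True` (it is dimensionally odd and, used for
bank matching, is dominated by its ~10³ magnitude). Bank: modes every
0.1 Cam over [0, E(16.2 kHz)], 60 geometric widths over [0.4, 20]
ERB_N; matching minimizes `(C−C_b)² + (S−S_b)²` with both terms in
Cam, ties toward the smaller mode then width. Per-pixel maps debias
each of the 11 depths and average the middle five (0.3–0.7) with no
surface smoothing.

A structural caveat established during validation: C and S are
scale-invariant in the curve, so a curve that effectively excites only
one or two stimuli (width ~1 ERB_N near a range edge; stimulus spacing
is ~4 Cam) determines its shape by a single amplitude ratio, and a
one-parameter family of (mode, width) pairs shares its (C, S)
*exactly*. Within such families the matched mode is arbitrary; with
the default bank, noiseless recovery is ~0.05 Cam for moderate widths
at interior modes but can err by several Cam for narrow edge curves,
and by 0.1–0.4 Cam for very wide curves (width-grid discretisation).
The debiasing still removes the bulk of the centroid's edge bias
(median edge error 0.37 vs 2.09 Cam in `analysis/02_debias_demo.py`),
which is its purpose.

Tuning widths: curves are recentred by integer index shifts so the
centroid lands on the nearest stimulus position (vacated samples are
treated as missing — the handling is not specified in the source
description), averaged over all 11 depths, smoothed per aligned sample
map (3-mm FWHM, mask-aware normalized convolution), and fitted with
`h·exp(−(x−m)²/2σ²) + b`, σ ∈ [0.4, 20], b ≤ 0, h ≥ 0. The fit is a
variable-projection least squares: coarse (mode, width) grid with the
(h, b) pair solved in closed form under its sign constraints, then a
vectorised Levenberg-damped Gauss–Newton polish on (mode, width)
(≤400 iterations, early stop at step < 1e-8); flat or degenerate
pixels are NaN. An exhaustive 4-parameter grid search serves as the
independent oracle in tests.

Split-half reliability correlates debiased maps from two disjoint data
halves; in the synthetic pipeline the halves are the even/odd depth
subsets (independent noise realisations of the same maps), which is
why the synthetic r (~0.93) is far above values typical of real
split-half designs.

## Gradients and reversals

Sobel fields use the standard 3×3 kernels; pixels whose 3×3
neighbourhood leaves the mask are invalid. Direction analysis uses
per-depth gradient fields averaged across depths, unsmoothed; reversal
detection smooths the field first (6-mm FWHM for individual
hemispheres; group maps stay robust down to 2–4 mm). For each pixel
and each orientation θ ∈ {0,…,179}°, the gradients of the two
straddling neighbours (nearest-pixel sampling at ±(cos θ, sin θ),
the default; the original sampling scheme is unspecified) are
projected onto θ; a strict sign change counts, and pixels with ≥10
counting orientations form the reversal mask (the count≥criterion
reading of the "10°" threshold). Denomination tests whether the
preferred frequency is a local extremum along the axial mean of the
detected orientations. Clustering is 8-connected per denomination with
orientation from the SVD of pixel coordinates; disconnected segments
merge when axes agree within 20° and endpoint gaps are ≤3 mm (both
tolerances are ours; the original joining rule is not described).

## ROI geometry and group statistics

The HG frame takes the ROI pixel centroid as origin and the *second*
right-singular vector of the in-ROI curvature gradients as the long
axis (gradients point across the ridge); near-isotropic gradient
distributions (singular-value ratio < 1.05) are flagged. Core ROIs
threshold the tuning-width (below) or myelin (above) map at the
midpoint between the TE1.0 mean and the anterior∪posterior non-core
mean (the all-TE1 alternative by flag); both HG and gradient ROIs are
algorithmic here, with manual masks accepted as overrides. Gradient
ROIs fill the bands between the low reversal and each high reversal,
with border positions interpolated along the axis and the mediolateral
ends clipped by the responsive mask. Axial quantities are processed
via angle doubling throughout. Circular CIs use the Upton/Zar
construction (the CircStat formula); coverage is verified by
simulation (95% ± 1.5% at κ = 4, n = 24). Consistency testing smooths
the frame-aligned fields (3 mm), applies the one-sample Hotelling T²
per pixel (p from `F = (n−2)/(2(n−1))·T²` on (2, n−2) dof), and
FDR-adjusts over the responsive union.

## Structural maps

MTR is `(M0 − MSAT)/M0` (invalid where M0 ≤ 0). Residualization is
per-depth OLS on centred covariates with the fitted intercept added
back, so maps keep the mean level needed for thresholding (whether the
original processing preserved means is unstated; this is our
documented choice). Only linear covariate removal is performed. In the
synthetic data the thickness ridge coincides with the core ellipses by
construction, so the per-depth nuisance R² (~0.3) runs far above the
2–10% of real data; the regression is exercised, not calibrated.
Group maps average depths 0.3–0.7 and smooth minimally (2 mm).

## Known limitations

- The (C, S) bank matching is non-identifiable for narrow tuning at
  the stimulus-range edges (see above); estimates there are best
  treated as "outside/at the edge of the range" rather than point
  values.
- Gradient ROI borders assume one dominant low reversal near the HG
  axis with high reversals on both sides; hemispheres missing either
  side fail loudly rather than guessing.
- The cohort shares one grid; spherical-normalization error, a real
  source of group-map blur, is not modelled.
- Reversal detection operates on flattened grids; geodesic gradients
  on curved meshes are out of scope.
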