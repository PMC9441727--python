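# Methods

## Signal model

Per voxel the diffusion-weighted attenuation is a two-compartment
(bi-tensor) mixture

```
A(b, g) = S(b, g) / S0 = (1 − f) · exp(−b · gᵀ D g) + f · exp(−b · d_w)
```

* `f` — free-water fractional volume, dimensionless, in [0, 1];
* `D` — tissue diffusion tensor (mm²/s), symmetric positive definite;
* `d_w` — free-water diffusivity at body temperature, fixed at
  `3.0e-3 mm²/s` (configurable, never fitted);
* `b` — diffusion weighting (s/mm²); the target acquisition is a single
  shell at b = 1000 with 64 approximately uniform directions and one b0.

FA-t is the standard fractional anisotropy of the fitted tissue tensor,
computed from its eigenvalues; an all-zero tensor is defined to have FA 0.

## Fitting

Attenuations are computed against the mean of the b0 volumes and clipped to
[0, 1]; voxels with non-positive S0 or all-zero signal are excluded from the
fit mask.

**Initialization.** `f` is interpolated from the observed mean diffusivity
(log-linear DTI fit) between an assumed tissue floor `MD_low = 0.6e-3 mm²/s`
and pure water, clamped to [0.05, 0.95]; the tensor is then initialized by a
log-linear DTI fit on the free-water-corrected attenuation
`(A − f·e_w)/(1 − f)`.

**Optimization.** Projected, damped Gauss–Newton on the 7 parameters
(f plus 6 unique tensor components, lower-triangular order
Dxx, Dyy, Dzz, Dxy, Dxz, Dyz). After each step `f` is clipped to [0, 1] and
the tensor is projected by eigenvalue clamping to
`[0.1e-3, 2.5e-3] mm²/s`. Per-voxel backtracking (step halving on the
projected iterate) makes the objective non-increasing on every voxel;
iteration stops when the relative objective change drops below `tol = 1e-6`
or after `max_iter = 200` iterations, and non-converged voxels are flagged
and keep their last iterate. Gauss–Newton was chosen over plain gradient
steps because the single-shell objective has a badly conditioned valley in
the (f, mean-diffusivity) plane; first-order steps stall there, while
Gauss–Newton reaches the noise-free optimum in ~20 iterations (measured
recovery error < 1e-4 in both f and FA-t across f ∈ [0.1, 0.8] ×
FA ∈ [0.2, 0.8]).

**Regularization.** The "regularized" part of the fit is an isotropic
first-difference (graph Laplacian, 6-neighbor) penalty on the f field with
weight `lambda_reg` (default 0.5). With `lambda_reg > 0` the fit alternates
a per-voxel tensor Gauss–Newton step with an exact sparse solve of the
quadratic surrogate in f, `(diag(curvature) + 2λL) δ = −∇`, globally
backtracked on the true coupled objective (still monotone). The default
weight makes the penalty comparable to the data term for adjacent-voxel f
differences around 0.1; fitted region means are insensitive to λ over
[0.1, 2]. `lambda_reg = 0` gives the purely voxelwise fit used for all
ground-truth (noise-free) comparisons.

### Known limitation: single-shell identifiability

With one shell, f is only weakly identified: raising f while lowering the
tissue mean diffusivity changes the predicted signal very little. On a
500-voxel phantom at SNR 30 the profile objective over a collective f shift
(with the tensor re-fitted) varies by less than the noise-induced tilt, so
any likelihood-driven estimate inherits the position set by its
initialization. Concretely, the initializer's tissue floor (0.6e-3) sits
below the phantom's tissue MD (0.7e-3), which biases f upward by roughly
`0.105 · (1 − f)` regardless of the regularization weight. Noise-free data
do not have this problem (the fit recovers f and FA-t to better than 1e-3),
and ROI-*contrast* analyses are largely immune because the anchor bias is
shared across regions. Multi-shell acquisitions remove the degeneracy but
are out of scope here.

## Phantoms and simulated signals

`make_phantom` builds a 2 mm isotropic grid with ellipsoidal WMH lesions, a
box-shaped WM mask (2-voxel margin, minus optional ventricles and lesions),
and two distance-driven fields: `f_true = fw_profile(d)` and a tissue
tensor with fixed mean diffusivity `0.7e-3 mm²/s` (typical white matter)
whose FA equals `fa_profile(d)`, where `d` is the Euclidean distance
transform to the nearest lesion voxel, clamped to [0, 16] mm. The Euclidean
transform is deliberately a different ruler than the city-block rim
construction, so rim binning is tested independently. Tensor principal axes
are seeded-random per voxel; profile values must lie in [0, 1] (FA is
internally capped at 0.995 to keep the tensor positive definite). Outside
the WM/lesion support voxels are pure free water.

The default pipeline profiles put the FW decay scale at 4 mm (elevated
through ~8 mm) and the FA peak at 3.2 mm, i.e. inside the second (2–4 mm]
band — matching the qualitative spatial structure the analysis is designed
to detect.

`simulate_dwi` evaluates the bi-tensor signal exactly and, at finite SNR,
applies Rician noise, `sqrt((S + n1)² + n2²)` with `n1, n2 ~ N(0, S0/SNR)` —
the standard magnitude-MRI model; SNR (default 30) is defined on b0.
`snr = inf` returns the exact forward signal.

## Image-free cohort generator

`simulate_cohort_rois` produces the subject × region long table directly:

```
outcome = region mean + covariate effects + subject intercept + residual
```

with 9 regions (WMH core + 8 rims). Covariates emulate the study
population: sex/smoking/diabetes/hypertension Bernoulli at 45.8 / 15.7 /
8.1 / 68.7 %; age a truncated normal on the 45–74-year recruitment window
(loc 70, scale 12) whose median is ~64 years; brain volume ~N(1483, 150) ml;
lesion volume log-normal with median 0.66 ml (σ_log = 1.3), giving a WMH
load (100·lesion/brain) with median ≈ 0.045 %. Default region profiles
follow the published adjacent-contrast pattern (FW stepping down from
~0.36 in the lesion to a ~0.10 NAWM baseline, FA-t lowest in the lesion and
peaking at the 4 mm rim); default covariate effects carry the published
signs with magnitudes small enough that outcomes never hit the [0, 1] clip.
Both SDs (random intercept, residual) default to 0.02 outcome units.

`recovery_profiles()` returns the extent-recovery study conditions: FW
elevated through the fourth rim and FA-t altered through the sixth, every
nonzero adjacent difference at 3 residual SDs (the lesion-boundary FW step
uses the published 0.166).

What the generator does **not** emulate: spatial correlation of ROI means
within subject beyond a shared intercept, registration and segmentation
error, scanner artifacts (eddy currents, motion, k-space effects), lesion
shape complexity, and any T1/FLAIR contrast. Passing tests therefore
demonstrate the statistical machinery and geometry under the stated model,
not robustness to those real-data effects.

## Rim geometry

Lesion masks are resampled from 1 mm to 2 mm by block averaging with a 0.5
(majority) binarization threshold. The subject-level minimum size rule —
fewer than 4 voxels (0.032 ml at 2 mm isotropic) excludes the subject — is
the default; a per-lesion variant exists but is off by default. Rims are
built by repeated one-voxel dilation with the face-connectivity (6-neighbor)
element: each shell, minus already-labeled voxels, intersected with the WM
mask, becomes the next rim. Face connectivity makes shell k exactly the set
of voxels at city-block distance k (one shell = 2 mm; 26-connectivity would
make diagonal steps 3.46 mm thick). Growth proceeds through non-WM voxels;
the WM filter applies per shell. Empty rims are allowed, recorded in the
atlas provenance, and dropped (not zero-filled) at extraction, since a
zero would masquerade as data in the mixed models.

Periventricular vs deep lesions: a connected component (26-connectivity) is
periventricular iff its minimum Euclidean distance to the ventricle mask is
≤ 10 mm (configurable; the boundary case counts as periventricular).

## Statistics

**Mixed models.** One model per outcome: fixed effects are the 9-level
region factor in forward-difference coding (coefficient i = mean(level i) −
mean(level i+1); the coding matrix has entries `(k−j−1)/k` above the
diagonal block and `−(j+1)/k` below) plus age, sex and log WMH load; a
random intercept per subject; REML estimation via statsmodels MixedLM; Wald
z p-values (with ≈ 200–900 subjects × 9 regions the small-sample df
correction is immaterial, verified by a null simulation whose per-contrast
type-I error is statistically indistinguishable from 0.05). No
multiple-testing correction; effects are significant at p < 0.05.

**Penumbra rule.** The merged "WMH-FW-penumbra" is the contiguous run of
rims starting at the lesion boundary for which the contrast on each rim's
*outer* side (rim k vs rim k+1) has p < α; the outermost rim, which has no
outer transition, falls back to its inner one. This is the reading that
reproduces both published extents from the published p columns — 8 mm for
FW (8–10 mm transition significant, 10–12 mm not) and 12 mm for FA-t — and
it is monotone in α. The alternative inner-transition prefix rule is
available as `rule="inner"`. Note the rule's over-extension probability is
exactly the α-rate of the first null transition (~5 % per analysis); this
is inherent to delimiting by unadjusted sequential tests.

**Risk models.** OLS of the subject-level WMH mean and merged-penumbra mean
(voxel-weighted across member rims when counts are available, otherwise the
unweighted mean of rim means) on age, sex, log WMH load, smoking, diabetes
and hypertension. Both raw and x-standardized coefficients (raw × covariate
SD) are reported, since either convention may be wanted for "standardized
β". Collinear designs raise with the condition number.

**Supplementary analyses.** Quartile comparison: subjects ranked by lesion
volume (ties broken by stable subject order); bottom and top quarters each
get the full mixed-model + penumbra treatment. Normality screening uses the
large-sample thresholds |skewness| < 2 and |excess kurtosis| < 7.

## Problem sizes

The test suite and acceptance script use deliberately compact problem
sizes: 16–22³ phantom grids (≈ 6–8 k fitted voxels), 500-voxel recovery
grids, cohorts of 200 subjects, 100 replicates for extent recovery and 1000
for the null-calibration study. These sizes were chosen so the entire
verification runs on a laptop-class single core in a few minutes while
keeping every Monte-Carlo margin (binomial CIs, 2-SE recovery bands) at its
nominal interpretation.
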