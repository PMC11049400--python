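# Methods

## Scope and data model

All volumes are index-ordered `(slice, row, column)` with per-axis spacing
in millimetres; NRRD is the on-disk format (read/written through
SimpleITK). A dynamic series is an ordered list of same-geometry volumes
with strictly increasing acquisition times. ROI masks (tumor, healthy,
vessel) share the series geometry and are propagated across the series as
identity copies: same-session perfusion scans share the scanner grid, so
the geometry-equality precondition replaces registration and visual
checks. The package does not model patient motion between scans.

## Synthetic phantom cohort

The phantom generator defines the study conditions under which every
downstream stage is tested.

**Arterial input function (AIF).** A first-pass gamma-variate,
`A ((t-t0)/(alpha*beta))^alpha exp(alpha - (t-t0)/beta)`, whose peak value
is exactly `A` at `t = t0 + alpha*beta`. Defaults `alpha = 3`,
`beta = 3.5 s`. Each patient draws the peak time uniformly from 15–26 s
and the amplitude from 520–827 HU — the acquisition ranges this pipeline
targets — and the bolus arrival `t0` follows. The recirculation tail is
omitted; observed first-pass curves are well approximated without it and
the phase rules only need one rise, one peak and one decay.

**Scan timing.** 30 scans by default: the first 20 at 1.5 s intervals,
the remainder at 3 s, starting at t = 0 (injection).

**Tissue kinetics.** One-compartment uptake,
`baseline + k_in * int aif(s) exp(-k_out (t-s)) ds`, evaluated with an
exponential integrator on a 0.05 s grid (exact for piecewise-constant
AIF). Defaults: tumor `k_in = 0.010 /s`, `k_out = 0.025 /s` (fast,
intense uptake, ≈ +90 HU near peak — the prostate-cancer-like regime);
healthy tissue `k_in = 0.003 /s`, `k_out = 0.015 /s` (≈ +30 HU, slow).
Both share the 45 HU pre-contrast baseline, deliberately: before bolus
arrival the two classes are statistically identical, so any class
separation downstream is purely contrast-driven.

**Texture and noise.** A unit-variance Gaussian random field with two
correlation lengths (1.5 and 4 mm — multi-scale tissue heterogeneity, so
that wavelet sub-bands and fine-scale LoG responses carry signal)
multiplies an amplitude `25 + 0.25 * enhancement(t)` HU inside the tissue
ROIs; the enhancement coupling makes texture features genuinely
phase-dependent with known ground truth. Additive Gaussian voxel noise
(sd 20 HU, the low-dose CT regime) is drawn independently per scan.
Photon/Poisson noise physics, organ anatomy and MR signal equations are
out of scope; an MR-like phantom differs only in amplitude scale and
timing grid.

**Determinism.** Per-patient integer seeds are derived from the master
seed via `numpy.random.SeedSequence`; a fixed spec and seed reproduces a
cohort bit-identically.

What passing phantom tests do **not** show: performance on real anatomy,
partial-volume effects at vessel walls, motion, or realistic feature
covariance structure. The phantom establishes correctness of the
machinery and the direction of the contrast-phase effects, not clinical
effect sizes.

## Phase synchronization

The seven phases are defined on the vessel-ROI median intensity curve as
described in the README. Two readings of the verbal rules were open:

* *"scan closest to an increase of at least 15%"* is implemented as the
  **earliest crossing** of the 115% level, because the sentence describes
  an event and the washout mirror rule ("last scan with … at least 15%
  higher") unambiguously uses crossing semantics; a
  `nearest_to_threshold` option is provided in `PhaseSyncConfig`.
* *"center between"* two phases is taken on the **acquisition-time axis**
  (not scan index), because the inter-scan interval changes from 1.5 s to
  3 s mid-series; an `index` option exists. Ties break to the earlier
  scan; peak ties break to the earliest scan (first-pass peak).

The threshold is relative, so phase selection is invariant under pure
positive scaling of the curve but not under additive offsets (tested).
Curves with no 15% rise raise "no bolus detected"; curves that never fall
back raise "no washout detected"; a non-monotone assignment raises
"phase ordering violated". For MR series the same algorithm is applied to
the vessel curve (manual phase picking is not reproduced).

## Feature battery

Preprocessing follows the usual radiomics order: optional whole-volume
z-score normalization × 100 (MR preset), resampling to the target spacing
(cubic B-spline for the image, nearest-neighbour for the mask; skipped
when the volume is already at target spacing), and cropping to the mask
bounding box plus a 10-voxel pad that supplies filter context.

Image sets: original; LoG at σ = 1–5 mm (CT) or 2–5 mm (MR), built from
explicit sampled Gaussian/second-derivative kernels with a zero-DC-gain
correction so a constant image maps to exactly zero, with per-axis sigma
in voxels `σ/spacing` and second derivatives per millimetre; and the
eight sub-bands of a single-level **undecimated** separable 3D wavelet
transform (Coiflet-1, `pywt.swtn` with `norm=True`), which keeps every
sub-band at the input size so the ROI mask applies unchanged and summed
sub-band energy equals input energy (Parseval; exact for even-sized
inputs, odd axes are edge-padded and cropped). Sub-band labels LLL…HHH
list the x, y, z filters in that order.

Discretization uses a fixed bin width anchored at the ROI minimum:
`level(x) = floor((x - min)/width) + 1`, width 25 HU (CT) or 5 (MR). The
intensity shift (1000 HU CT / 300 MR) enters only the squared-intensity
first-order features (Energy, TotalEnergy, RootMeanSquared), preventing
negative values from cancelling under squaring.

Per image set, 86 features: 18 first-order (population moments; Kurtosis
without the −3 correction), 22 GLCM (symmetric co-occurrence over the 13
unique distance-1 directions, normalized per direction, features averaged
over directions), 14 GLDM (26-connected dependence counts at threshold
α = 0, dependence size = 1 + matching neighbours), 16 GLRLM (maximal runs
per direction, averaged), 16 GLSZM (26-connected iso-intensity zones).
Shape features are excluded by construction — the mask is identical
across the series.

**Degenerate inputs** return defined sentinels plus a per-feature flag
rather than raising: a single-voxel ROI flags all GLCM features (NaN); a
single-gray-level ROI flags the correlation family with fallbacks
Correlation = 1, Imc1 = 0, InverseVariance = 0; a constant ROI flags
Skewness/Kurtosis (0). Flagged values are treated as missing by the
screen and imputed by the classifier. On the default phantom the smooth
LoG responses at σ ≥ 2 mm span less than one 25 HU bin and are flagged
this way — the expected behaviour for a fixed-bin-width battery on
low-contrast filtered images.

**Verification.** Every one of the 86 features is checked against an
independent brute-force reference implementation (explicit pair/run/zone
enumeration, written separately in the test suite) on 50 random 4×4×4
ROIs at 1e-6 relative tolerance, plus hand-traced micro-examples. The
reference shares the same published formula definitions and degeneracy
conventions; it is independent in implementation, not in convention.

## Temporal screen

Per feature and ROI: REML fit of `value ~ timepoint + (1|patient)` with
`statsmodels` `MixedLM` (the response is internally standardized for
numerical stability; the slope is reported back on the feature scale).
Timepoint enters as a numeric 1–7 covariate by default (one coefficient);
a categorical joint Wald-F option exists for non-monotone profiles. A
`(1|visit)` variance component is available for multi-visit designs.

`MixedLM` provides Wald z-statistics but no Satterthwaite degrees of
freedom; the timepoint test therefore uses a t (or F) reference with
residual df `N - n_groups - n_slope_terms`. For the balanced
within-patient design screened here this equals the Satterthwaite df
exactly, which the test suite confirms against R `lmerTest` (slope,
p-value and df agree on a shared fixture). Type-I error of the full
screen is calibrated on 1000 null features (7 patients × 7 phases): the
raw p < 0.05 rate falls in [0.03, 0.07].

Zero-variance or all-flagged features, and fits that fail across the
lbfgs/bfgs/powell optimizer chain, are marked excluded and removed from
the FDR universe (the same treatment given to non-converging energy
features in practice). Significance requires both p < α and BH-FDR
q < α (α = 0.05).

Profiles: per-phase means over patients, z-scored across the seven
phases with the sample (n−1) standard deviation; constant profiles return
zeros with a flag. Clustering: complete linkage on Euclidean distances;
the cluster count is a parameter, defaulting to the cut at the largest
relative gap between successive merge heights (minimum 2 when any merge
height is positive).

## Phase-wise classification

Instances are (patient, ROI) pairs at one phase; the label is the ROI
type. Leave-one-out cross-validation with L2-penalized logistic
regression, C = 1, lbfgs, max_iter = 2000, tol = 1e-6 (pinned for
determinism). Features are not standardized by default, matching
plain-default usage; a within-fold z-scaling flag exists because
unscaled penalized regression on features spanning many orders of
magnitude can be fragile. Missing/flagged values are imputed with the
training-fold median (never the held-out ROI). AUC is the Mann–Whitney
pair statistic with ties counted ½; the 95% CI uses DeLong placement
variances by default, with a class-stratified bootstrap alternative.

On the default phantom the pre-bolus AUC is tested against a one-sided
band (≤ 0.8) rather than a tight interval around 0.5: with 7 + 7 ROIs a
null LOO AUC has a standard deviation near 0.16 and is biased below 0.5,
so "chance level" at this n is a wide band. The peak-phase bound is
AUC ≥ 0.9.

## Problem sizes

Default cohort: 7 patients, 32³ voxel grids at 1 mm, 30 scans, two tissue
ROIs of ≈ 500 voxels — chosen so a full pipeline run (simulate → sync →
extract 1204 × 7 phases × 2 ROIs × 7 patients → screen → classify)
completes in about two minutes on one core. Extraction is cached on a
configuration hash so statistics options can be varied without
re-extracting.

## Known limitations

* Identity mask propagation assumes no inter-scan motion.
* The gray-level discretization is anchored at the ROI minimum; tools
  that anchor bins at absolute multiples of the bin width will differ on
  inputs whose minimum is not a bin-width multiple (conventions coincide
  for integer data at width 1, as used in the equivalence tests).
* The LoG filter uses explicit sampled-kernel convolution; recursive
  Gaussian approximations in other toolkits produce slightly different
  boundary behaviour.
* The mixed-model df is exact only for balanced within-subject designs;
  strongly unbalanced multi-visit data would need a full Satterthwaite
  implementation.
* DeLong CIs are degenerate (zero width) at AUC = 0 or 1; the bootstrap
  option behaves similarly at the extremes with small n.
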