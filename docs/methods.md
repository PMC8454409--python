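# Methods

This note documents the models, conventions and numerical choices behind
`perirad`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Compartment geometry

Peritumoral rings are defined by the spacing-aware Euclidean distance from
each voxel centre to the nearest tumor voxel centre (`scipy`'s exact
Euclidean distance transform). Ring *k* is the half-open shell
`(r_{k-1}, r_k]` with radii 5/10/15 mm by default, so every voxel belongs
to exactly one compartment and a voxel at distance exactly 0 is tumor.
Distance thresholding is mathematically equivalent to morphologic dilation
with a Euclidean structuring element but avoids discretizing the element on
anisotropic grids. Distances are snapped to 1 nm before thresholding so
voxels lying exactly on a radius land on the same side regardless of the
float path that produced the distance. Dilation is 3-D by default; an
in-plane 2-D mode is available (`mode="2d"`). If the 15-mm shell crosses
the grid boundary the rings are clipped with a warning rather than
rejected. A body window of [−300, 3000] HU (configurable) removes air-like
voxels from rings. Cases with fewer than 200 tumor voxels fail QC.

## Texture features

All families are computed per 2-D slice, on the slices that contain tumor,
over a reflection-padded bounding box around the tumor + 15-mm shell;
padding never contributes pooled pixels. 208 response maps:

* **gray (16)** — local mean, median, SD, range in 3/5/7/9-pixel windows.
* **gradient (40)** — per window: mean and SD of each gradient component,
  mean/SD/range/energy of the gradient magnitude, and mean absolute
  component values (10 measures × 4 windows). All vanish on constants.
* **haralick (52)** — per pixel, a symmetric GLCM over all distance-1
  neighbor pairs whose both endpoints lie in the window; the four offset
  directions are normalized separately and averaged; 13 metrics (contrast,
  correlation, energy, entropy, homogeneity, variance, sum-average,
  sum-variance, sum-entropy, difference-average, difference-variance,
  difference-entropy, first information measure of correlation) × 4
  windows. Quantization: 64 uniform levels over the processed crop's
  intensity range (shared by all four compartments — one quantization per
  slice keeps the maps reusable across compartments; a fixed range can be
  supplied instead). Conventions: entropies in bits (log2), correlation of
  a single-level window is 0, IMC1 is 0 when the marginal entropy is 0.
* **laws (20)** — the ordered pairs of distinct 1-D kernels
  {L5, E5, S5, W5, R5}; name `AB` applies A along axis 0 and B along
  axis 1 (E5L5 and L5R5 are distinct maps).
* **gabor (28)** — zero-mean complex Gabor kernels at 7 orientations
  (22.5°…157.5°) × 4 wavelengths (2, 4, 8, 12 px); magnitude response.
* **collage (52)** — per pixel, the dominant gradient orientation from the
  windowed structure tensor (equivalently the principal singular vector of
  the stacked window gradients), quantized into 64 bins over [0, π); the
  13 Haralick metrics applied to the orientation co-occurrence in the same
  window. Zero-gradient windows take bin 0.

Pooling uses five statistics: mean, median, population SD, Fisher–Pearson
skewness and excess kurtosis (plain biased moment estimators). A constant
pool has SD/skewness/kurtosis 0; an empty compartment yields NaN plus an
explicit flag — never a silent omission. z-scoring uses training-cohort
mean and population SD; zero-SD columns map to 0 and are flagged.

The per-pixel GLCM engine counts window pair co-occurrences by scattering
shifted code maps through `bincount` (O(window² · pixels) per direction)
and evaluates all 13 metrics vectorized over pixels; it is cross-checked
against an exhaustive pair-enumeration oracle to 1e−10 in the tests.

A note on the GLCM *correlation* direction: within windows much smaller
than the texture correlation length, local demeaning biases the
correlation estimate downward, more severely for smoother textures; with
the default phenotypes the physically expected ordering (smooth class
higher) holds for windows of ≥ 17 px and can invert below that. The
directional property test therefore uses window 17.

## Classification arm

Spearman pruning removes, from every pair with |rho| > 0.80, the feature
with the larger two-sided Wilcoxon rank-sum p-value. Because the rule is
order-dependent, pairs are processed by descending |rho| (ties:
lexicographic); this order makes the kept set monotone in the threshold.
Wilcoxon p-values use exact enumeration for two samples of ≤ 20 without
ties and the tie-corrected normal approximation otherwise.

MRMR uses the difference (MID) form with mutual information on quantile-
discretized features (4 bins); the MIQ ratio form is switchable. Stability
selection runs MRMR on each training fold of a seeded, stratified,
repeated CV (default 100 runs × 3 folds) and returns the 15 most
frequently selected descriptors (ties: better mean rank, then name).
Pruning is fit once on the training cohort, before the CV.

The classifier is pooled-covariance LDA (least-squares solver, weights
∝ Σ⁻¹(μ₁−μ₀)); a singular covariance falls back to Ledoit–Wolf shrinkage,
recorded on the model. The decision threshold (default 0.4 on the
positive-class posterior) is frozen at training and carried to validation.
AUC is the rank statistic with half credit for ties; its CI is a
stratified bootstrap (2,000 resamples by default, seeded).

## Prognosis arm

The penalized fit is an L1 Cox path (scikit-survival Coxnet) over 100
penalties spanning four decades below the all-zero penalty, solved with
internal column standardization (the glmnet default) so path entry order
does not depend on per-column scale. The penalty minimizes the
Verweij–van Houwelingen cross-validated partial likelihood
(fold contribution: loglik(all) − loglik(training part)) over 10
event-stratified folds; the naive held-out-fold partial likelihood is far
too noisy at ~10 subjects per fold. An all-zero solution is reported as an
explicit empty signature.

RRS is the linear combination of the selected z-scored features; the
high/low split uses the training-median cutoff, frozen and applied
unchanged to validation sets. Group comparisons report the Kaplan–Meier
curves (Greenwood variance; ties handled events-before-censorings), the
two-group log-rank test, and a Cox HR on the group indicator — both the
per-group HR and the per-unit HR of the continuous score are available,
since either scale may be quoted. Cox fits use lifelines (Efron ties) with
Wald CIs; fewer events than covariates triggers a warning. Univariable
screening tests each candidate (multi-level factors jointly, by
likelihood-ratio test) at α = 0.05 and passes the significant ones to one
joint fit; constant-within-subset dummies are treated as not evaluable.

A `select_signature_size` helper reproduces choosing the signature size by
the largest median-split HR on a designated validation set. Because that
rule consumes validation outcomes, its result carries a prominent
`validation-selection` provenance flag and the default pipeline selects
the penalty on training data only.

## Nomograms and evaluation

Nomogram points are proportional to each covariate's contribution to the
linear predictor, anchored so each covariate's minimum-hazard range end is
0 points and the largest |β|·range spans exactly 100; total points map to
survival at the configured horizons through the fitted baseline survival
(Breslow, as computed by lifelines at the covariate mean). The points
round trip: survival-from-points equals the direct Cox prediction to
1e−6. Multi-level stages enter nomograms as ordinal codes.

Harrell's C counts pairs whose earlier time is an event, crediting ties
0.5 (lifelines implementation, cross-checked against O(n²) enumeration).
The bootstrap C (default B = 1,000) refits the model per resample and
reports a percentile 95% CI; resamples without events are redrawn and
counted. Calibration bins patients by predicted survival at a horizon
(default tertiles at 2 and 5 years) and compares with the KM estimate and
Greenwood SE per bin; bins with nobody at risk at the horizon are flagged
not evaluable. Decision curves compute
NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t), with the treated group's event
probability at the horizon taken from the KM estimator so censoring is
handled; treat-all and treat-none references are included.

## Synthetic phantoms

Tumors are ellipsoids (default semi-axes 10 × 8 × 4 mm) centred on a
64 × 64 × 16 grid at 1 × 1 × 2.5 mm, constrained to leave a 16-mm margin
so the 15-mm shell fits. Texture is a Gaussian random field (white noise
smoothed to a target correlation length and normalized analytically to the
target SD) on the tumor and its 0–10 mm rim, plus, in the rim, a
sinusoidal ripple whose orientation is randomized per 8-mm in-plane patch.
Default phenotypes: positive — correlation length 3.0 mm, SD 8 HU, ripple
4 HU, tumor mean 90 HU; negative — 1.8 mm, 16 HU, 12 HU, 78 HU over a
40-HU background. The amplitude gap makes texture amplitude a leading
class discriminator and the rim ripple drives gradient-orientation
disorder, mirroring the qualitative contrast between homogeneous and
heterogeneous tumor phenotypes. Per-patient heterogeneity: log-normal
jitter of the texture amplitude (SD 0.25) and correlation length (SD
0.15), Gaussian jitter of the tumor mean (SD 6 HU), and ±15% axis scaling.

Clinical covariates are sampled independently from per-class frequency
tables modeled on an OPSCC cohort's training-split demographics; the
generator does not model covariate–texture dependence (none is stated to
exist, and planting it would entangle the arms).

Survival is a Weibull proportional-hazards model (shape 1 = exponential by
default, scale 6 years) with hazard ∝ exp(linear predictor); censoring is
an independent exponential whose rate is calibrated so a baseline subject
is censored with the configured probability (0.5 by default) — exponential
rather than uniform censoring because the censoring fraction then has a
closed form. Planted effects are log hazard ratios per *within-class* SD
of a named image summary (within-tumor mean/SD, rim SD, volume, neighbor
correlations), so each phenotype arm sees the stated effect size
regardless of the between-class summary gap. All randomness flows from one
root seed through named substreams (geometry, texture, survival,
covariates).

What the phantoms do **not** emulate: anatomy (no bones or airways),
scanner physics and noise spectra, segmentation variability, or
covariate–outcome confounding. Passing the end-to-end tests therefore
shows that the pipeline recovers signals of the planted kind at realistic
sample sizes — not that it would achieve any particular performance on
clinical CT.

## Desk-scale study configuration

The end-to-end recovery study mirrors the clinical design: training
100 pos / 80 neg, validation 237 pos / 45 neg, phantoms at 64 × 64 × 16,
repeated over 20 seeded replicates. To keep a replicate tractable on one
CPU the study uses a reduced texture vocabulary
(`TextureConfig.fast()`: gray + gradient + orientation-co-occurrence
families, window 3, 8 quantization levels — 540 descriptors) and 20-run
MRMR stability selection; the full 4,160-descriptor vocabulary and the
100-run protocol remain the library defaults and are exercised directly by
the unit tests. `scripts/acceptance.py` runs the same study at 5
replicates; `tests/test_acceptance.py` runs all 20.

## Known limitations

* 2-D slice-wise texture only; no 2.5-D/3-D kernels, no wavelet/shape
  features, no inter-scanner harmonization.
* The GLCM engine is exact but O(window² · pixels · levels); very large
  windows with 64 levels are slow (the full-vocabulary extraction of one
  desk-scale case takes seconds, not milliseconds).
* Decision-curve censoring handling assumes censoring independent of the
  predictions within the treated group.
* No competing risks, time-varying covariates, or proportional-hazards
  diagnostics beyond convergence warnings.
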