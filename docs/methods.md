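# Methods

This note records the models, numerical choices and design decisions behind
`ssmpet`, and what the phantom-based validation does and does not establish.

## Kinetic modelling

### Model and conventions

The simplified reference tissue model (SRTM) describes a voxel's activity as

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a t)](t),
    k2a = k2 / (1 + BPND),  k2' = k2 / R1,

where `R1` (unitless) is relative delivery, `k2` and `k2'` (min⁻¹) are tissue
and reference efflux rates, `k2a` (min⁻¹) the apparent efflux rate and `BPND`
the non-displaceable binding potential. Frame times are kept in seconds and
rate constants in min⁻¹; the conversion happens once, inside the convolution.
The literature quotes the apparent-efflux fitting range 0.01–0.3 without
units; min⁻¹ is the field convention and is what this package assumes.

The convolution is evaluated on a uniform 1 s grid by the exact recursion for
a piecewise-linear input against an exponential kernel (each step applies the
closed-form integral of the linear segment), so noiseless forward data are
reproduced by the fit to machine precision. Frame values are *time-averages*
over the frame interval, not instantaneous samples, both in the forward model
and in the fit design matrix; frame averages are taken from the running
trapezoidal integral and support non-integer frame boundaries.

### Two-stage fitting

`fit_srtm` solves, for each candidate `θ = k2a` on a grid, the 2-parameter
weighted linear least squares `C_T ≈ R1·C_R + φ·[C_R ⊗ e^(−θt)]` (weights =
frame durations) and keeps the residual-minimising `θ`; then `k2 = φ + R1·θ`,
`BPND = k2/θ − 1`.

`fit_srtm2_voxelwise` implements the production map estimator:

1. the reference TAC is the mean over reference-mask voxels;
2. SRTM is fit per voxel on a widened grid (see below);
3. `k2'` is fixed at the median of `k2/R1` over voxels with `BPND > 0.05`
   (the selection is used *only* for this median; the final map is fit on
   every mask voxel, since nothing requires the map itself to be restricted);
4. SRTM2 — `C_T = R1·[C_R + (k2' − k2a)·basis]`, one linear parameter per
   candidate — is refit per voxel on 80 log-spaced `k2a` values in
   [0.01, 0.3] min⁻¹.

Grids are logarithmic (basis-function practice; the literature gives only the
range and count). The stage-1 grid extends the SRTM2 grid geometrically to
[k2a_min/2, 2·k2a_max] with the same ratio, so the two grids share their
interior points: an apparent efflux rate representable in stage 2 is exactly
representable in stage 1, which makes noiseless recovery exact through both
stages.

### Reference-curve reconstruction

The measured reference TAC is a set of frame averages, but the convolution
basis needs a fine-grid curve. The curve is reconstructed by iterative
refinement: start from linear interpolation through the frame midpoints
(anchored at zero activity at t = 0) and repeatedly add the frame-average
residual to the midpoint knots until the reconstruction's own frame averages
match the data (typically < 30 iterations to 1e−12). Two simpler schemes were
rejected: plain midpoint interpolation leaves ~2% errors around the bolus
peak which the `k2'`-sensitivity of SRTM2 amplifies ~20-fold into
reference-region R1 bias, and the exact boundary-matching piecewise-linear
solve is zigzag-unstable on decaying curves.

### Statistical behaviour under noise

R1 from the free 3-parameter SRTM fit is intrinsically ill-conditioned: a
Cramér–Rao computation on the phantom's gamma-variate reference curve shows
that at 5% frame noise no weighting or frame schedule brings the R1 standard
error much below ~7–10% (the delivery/efflux trade-off is nearly collinear at
late times). This is precisely the motivation for SRTM2: with `k2'` fixed the
median |R1 error| at 5% noise drops to ~4%. The package therefore treats the
SRTM2 refit as *the* R1 estimator; the free SRTM fit exists to seed the
`k2'` median.

Because the reconstruction and the fit are most sensitive to the bolus rise
and peak, the default phantom frame schedule uses 5 s frames through the
peak (24×5 s, 12×10 s, 8×30 s, 6×60 s, 5×120 s, then 300 s frames).

### ePIB and SUVR

ePIB images are duration-weighted means of the frames overlapping a window
(closed on both ends; partial overlaps contribute pro-rata), divided by the
same quantity averaged over the reference region. Both early-window presets
are shipped — 20–130 s and 20–120 s — because the quoted window differs
between sources; 20–130 s is the default. The 1–8 min preset is the longer
pseudo-perfusion window. SUVR divides a static image by its reference-region
mean. Both are invariant to global multiplicative rescaling of the input.

## Pattern derivation (SSM/PCA)

Images are masked and stacked as a voxels × subjects matrix; each column is
centred by its own mask-mean ("centred per subject" is read as subtracting
the subject's scalar mean; row-profile double-centering variants are out of
scope); the mean HC column profile is then subtracted from every column and
stored. No log-transform is applied by default — the classical formulation
log-transforms, but quantitative R1 maps cannot be assumed lognormal — and a
`log_transform` flag restores the classical behaviour.

PCA runs through the subjects × subjects Gram matrix (equivalent to the full
SVD, cheap when voxels ≫ subjects; the equivalence is property-tested).
Component signs are fixed by making each component's largest-|loading| voxel
positive. The candidate pool is the minimal prefix of variance-ordered
components whose cumulative explained variance reaches the target (default
50%); later components cannot re-enter.

Stepwise selection is forward-only with strictly-decreasing AIC acceptance,
ties broken toward the lower component index. Perfect separation — common
with ~30 subjects and strong effects — is handled by a fixed small ridge
(α = 0.01 on the standardised slopes) used only when the unpenalised
maximum-likelihood fit diverges; the AIC is always computed from the
*unpenalised* log-likelihood at the converged coefficients. An empty
selection (no component lowers the AIC below the intercept-only model) is an
error, not a silent null pattern.

The disease pattern is Σ βᵢ·PCᵢ over the selected components, unit-normalised
and sign-fixed so mean(AD scores) > mean(HC scores). Its "variance explained"
is the summed variance fractions of the included components. Because the
doubly-centred matrix has zero-mean columns, the pattern weights sum to zero
over the mask — which is what makes the scoring identity below exact.

### Scoring, LOOCV and Z-standardisation

A raw score is the inner product of the pattern with an image that has been
masked, centred by its own mask-mean and had the *training* HC mean profile
subtracted (prospective subjects get exactly the training-time preprocessing;
whether the original formulation subtracted the HC profile from test images
is not documented, so this package picks the construction that makes
training and prospective scoring identical). Consequences, both tested to
1e−8: adding `t`·pattern to an image raises its raw score by exactly `t`, and
global additive shifts leave scores unchanged.

LOOCV re-derives the pattern on each n−1 subset, sign-aligns it to the
full-cohort pattern by cosine, and scores the held-out subject; the per-fold
cosine to the full pattern is reported as a stability measure. Scores are
standardised as `z = (raw − mean(HC LOOCV)) / sd(HC LOOCV)` (sample SD); the
"mean standard deviation of the LOOCV HC group" phrasing is read as "mean and
standard deviation", which is the only reading that makes the HC LOOCV
Z-scores mean 0, SD 1 by construction.

Regional summaries report voxel count × voxel volume (cm³), mean and SD of
the pattern weights per atlas region and per combined lobe, inside the
analysis mask; regions empty under the mask are reported as empty rows.

## Comparison and score statistics

Pattern comparison treats voxels as independent observations (spatial
autocorrelation is acknowledged, not corrected — matching voxel-level
practice). Joint histograms use equal-width bins spanning each pattern's own
min–max range, 64 bins by default (neither is externally specified), with
counts conserved by construction and a log10 display that masks empty bins.
The regression convention puts the metabolic pattern on the x-axis.

ROC analysis sweeps thresholds at midpoints of adjacent distinct scores plus
±∞ sentinels; the AUC is the trapezoidal area along the sweep, which equals
the Mann–Whitney concordance probability exactly (property-tested); the
Youden threshold maximises sensitivity + specificity − 1 with ties resolved
to the lowest threshold. The 95% AUC interval is a stratified percentile
bootstrap (2000 resamples, seeded) by default because the CI method is not
externally specified; DeLong is available behind a flag.

ANOVA is one-way fixed-effects over the four clinical groups on Z-scores per
image type; Tukey HSD adjusted p-values come from the studentized-range
distribution with the pooled MSE (for k = 2 they reduce to the plain t-test,
tested to 1e−8). Bland–Altman takes differences y − x, limits of agreement
mean ± 1.96·SD, and regresses the difference on the pair mean by default
(standard practice); regressing on x instead is available via a flag since
the reference-anchored variant is also in use.

## Synthetic phantom cohorts

The generator exists to make every stage testable by recovery, emulating the
statistical structure the pipeline consumes rather than PET physics.

* **Atlas/mask**: an ellipsoidal mask partitioned into contiguous regions by
  seeded Voronoi assignment; the lowest region plays cerebellar grey matter
  (the reference); others are assigned cyclically to the four cortical lobes.
* **Template**: piecewise-constant per lobe, Gaussian-smoothed (mm FWHM),
  masked, unit-normalised; affected lobes negative. Smoothing is applied to
  template and noise but not to the baseline, keeping ground truth
  interpretable.
* **Static cohort**: `image = g·baseline·(1 + z·template) + noise` with
  `g ~ lognormal(0, 0.05)`, `z ~ N(mean[group], 0.5)`, smoothed iid Gaussian
  noise (SD 0.01 in baseline units ≈ 1%), baseline 1 ± 10% smooth variation.
  Group expression means default to HC = 0, MCI− = 0.3, MCI+ = 1.0, AD = 2.0
  — a fixture choice mirroring the clinical ordering of score distributions.
  Group sizes default to 15/11/10/16 (AD/MCI+/MCI−/HC). Generated images are
  "raw": noise precedes any SUVR-type normalisation downstream. A `z_table`
  argument pins per-subject severities, which is how one disease process is
  imaged through two modalities in the comparison studies.
* **Dynamic cohort**: per-region SRTM forward solutions driven by a
  gamma-variate reference curve `A·(t/τ)^α·e^(−t/τ)` (defaults A = 10, α = 2,
  τ = 80 s; peak at 160 s, within the first third of the scan). Region
  kinetics keep `k2/R1 = k2'` consistent across tissue, as the
  reference-tissue model assumes, with apparent efflux snapped onto the SRTM2
  basis grid so that noiseless recovery is exact.

What phantom-passing shows — and does not. Recovery on these phantoms
verifies the algebra and numerics of every stage under the model's own
assumptions (shared anatomy, region-homogeneous kinetics, Gaussian noise,
no attenuation/scatter/PSF, no partial-volume effects, no registration
error). It does not establish performance on real scanner data, where those
effects, plus anatomical variability and model misfit, dominate.

## Problem sizes used in validation

The validation suite runs on a 16³ grid (~1 500 mask voxels, 6 regions),
52-subject cohorts, 200 simulated curves for kinetic recovery, 20 cohort
seeds for pattern recovery, 1 000 null simulations for the ANOVA type-I
check and 10⁴ pairs for Bland–Altman coverage — sizes at which every
recovery margin above is comfortably resolved while the whole battery runs
in about a minute.

## Known limitations

* No spatial normalisation, segmentation or DICOM ingestion: all images must
  already share one grid.
* Voxel independence is assumed wherever voxels enter a statistic.
* The stepwise candidate pool is strictly the variance prefix; alternative
  pools (all components, re-entry) are not offered.
* The ridge fallback's AIC is an approximation at separation (the
  unpenalised likelihood has no finite maximiser there).
* `BPND` estimates are reported but the pipeline is tuned for R1; no
  Logan/SUVR-based binding quantification is included.
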