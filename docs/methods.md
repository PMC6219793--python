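# Methods

This note documents the models, numerical choices and limitations of the
`emodyn` pipeline: what each stage assumes, which knobs matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Profile ingestion and resampling

A drawn intensity profile is an ordered list of (x, y) device-unit points
over the 90 s read-and-think epoch (30 s reading + 60 s thinking; the
drawing grid's x-axis is divided proportionally). Trackball traces can
backtrack, so curves are first made functions of x by keeping the *last* y
drawn at each x (the final stroke reflects the intended value), sorting by
x, and clipping y at 0. The piecewise-linear interpolant is then evaluated
at `n_samples` equally spaced abscissae spanning the drawn x-range, with
boundary values held outside it; the drawn range maps affinely onto
[0, 90] s. `n_samples` is derived as floor(epoch / TR) = floor(90 / 2.04)
= 44 rather than hard-coded, because the grid exists to align one intensity
sample with each acquired volume of the epoch. Intensities are kept in
device units (no rescaling of the 7-interval axis); every downstream
statistic that is compared across analyses (standardised β, t) is invariant
to that scale.

Only negative-feedback trials are analysed; the canonical long-format CSV
(participant, run, trial, perspective, valence, x, y) can be remapped onto
other export headers via a column map.

## Two-component NNMF

The 384 × 44 profile matrix is factorised as X ≈ WH, W, H ≥ 0, k = 2, by
Lee–Seung multiplicative updates for the Frobenius objective. Because the
problem is non-convex, the fit restarts from 50 random nonnegative
initialisations (uniform [0.1, 1] scaled to the data magnitude) and keeps
the restart with the lowest final ‖X − WH‖_F; each run stops when the
objective decrease falls below a relative tolerance of 1e−9 or after 2000
iterations. The objective is non-increasing across iterations (a property
the tests assert per iteration). A small epsilon (1e−12) in the update
denominators guards divisions; an all-zero X yields W = 0 with
conventionally normalised loadings.

Scale convention: loading rows are normalised to unit Euclidean norm with
the scale absorbed into the scores, so scores are comparable across
components. Component identity is assigned by temporal shape, since NNMF
component order is arbitrary: the component with the smaller loading-weighted
mean time (temporal centroid Σtᵢhᵢ/Σhᵢ) is explosiveness, the other
accumulation; exact centroid ties go to the component with the larger final
loading (accumulation). Percentile reconstructions (10th/mean/90th score on
one component, mean on the other) use the linear-interpolation percentile
definition, matching common statistical software.

A note on identifiability: an exact nonnegative factorisation is unique only
when the data touch the boundary of the nonnegative cone — some trials
nearly pure in one component, loadings with non-overlapping near-zero
regions. Real profile sets contain such trials (episodes that return fully
to baseline have ≈ 0 accumulation), and the test oracles construct them
explicitly; on interior data the fitted loadings can rotate slightly within
the cone at identical reconstruction error. All replication-relevant
statistics downstream are computed from the fitted model itself and do not
depend on resolving this ambiguity.

`extract_scores_from_subprofiles` inverts stored subprofile tables
(score × loading per trial) by the dominant singular direction,
sign-corrected and clipped nonnegative; scores are recovered up to one
global scale per component, and a rank-1 energy fraction below 1 − 1e−6
triggers a diagnostic warning.

## Design matrix

Each run is modeled with boxcar regressors for the perspective-instruction
screen (self-paced), the 5 s announcement, the two 90 s feedback epochs
(negative, neutral — each one boxcar spanning reading + thinking), and the
self-paced drawing period; relaxation periods are unmodeled and act as the
implicit baseline. Instruction and drawing durations come from the event
table, not constants. The two subprofile regressors place each negative
trial's 44 samples across that trial's epoch (sample i on
[onset + i·epoch/44, onset + (i+1)·epoch/44), held piecewise constant);
they are *not* mean-centered and *not* orthogonalised against the
feedback boxcar — variance shared among the boxcar and the two subprofile
columns is resolved by the multiple regression itself.

HRF: the canonical double-gamma (peak delay 6 s, undershoot delay 16 s, unit
dispersions, peak:undershoot 6, 32 s kernel — the SPM canonical parameters),
discretised at TR/16. Regressors are built on this microtime grid and
sampled at volume midpoints. Numerically, events are laid down with
fractional bin coverage and the convolution kernel is sampled at bin
midpoints, making the construction second-order accurate in the bin width:
doubling the bins changes columns by well under 0.1% RMS. The kernel is
normalised to unit peak (on a dense grid, so the scale is independent of
the bin width); regressor scale cancels in all t statistics.

Drift: a discrete-cosine basis with periods above 200 s,
cos(πk(2n+1)/(2N)) for k = 1..K, K = floor(2·N·TR/cutoff) (13 columns for
the average 684-volume run), excluding the constant. The basis is applied
by projecting it out of both data and regressors, which is exactly
equivalent for OLS to entering the columns as nuisance regressors (asserted
in tests); residual degrees of freedom subtract the K drift columns. The
six motion realignment parameters enter as confound columns. Assembly is
order-deterministic ([5 task boxcars, explosiveness, accumulation, motion×6,
intercept]); all-zero task columns and linearly dependent columns (scanned
left to right) are hard errors naming the offenders.

## Estimation and inference

First-level: voxelwise OLS on in-mask voxels, β̂ = (XᵀX)⁻¹XᵀY after drift
projection, σ̂² = RSS/df with df = n − rank(X) − K. Contrasts give
t = cᵀβ̂ / √(σ̂²·cᵀ(XᵀX)⁻¹c). Serial correlation is not prewhitened (an
OLS model); the group level operates on per-subject summary maps (runs
averaged per subject), whose random-effects t-tests are insensitive to
first-level variance misestimation to first order.

Group: voxelwise one-sample t vs 0, df = n_subjects − 1, two- and one-sided
p. Zero-variance voxels are excluded (all-zero) or flagged with p = 0
(nonzero constant). Thresholding is one-sided positive at p < .001
(uncorrected) with clusters of ≥ 10 voxels kept (the extent rule is a
config parameter; ≥ is used), 18-connectivity (face + edge, the SPM
convention; configurable). Voxelwise FDR uses Benjamini–Hochberg over
in-mask voxels. Cluster-level FWER is computed by sign-flip permutation of
subject maps against the max-cluster-size null — exact under a symmetric
null — rather than Gaussian-random-field theory, which needs smoothness
estimation and large-lattice assumptions that small simulated grids (and
many real grids) violate; requesting more permutations than the 2^n
distinct sign patterns is an error suggesting exact enumeration.

ROI tests average each subject's second-level betas over mask voxels and
test the subject means with a one-sample t, one-sided in the hypothesised
positive direction, Bonferroni-multiplied by the family size (4 for a
2-ROI × 2-regressor table, 6 for a 3 × 2 table; the family is a config
parameter since table compositions vary). One-sidedness means a strongly
negative mean reports p = 1.00. The insula splits into anterior (world
y > −10 mm) and posterior (y ≤ −10 mm) at voxel centers via the mask's
affine; y exactly at the split goes posterior (documented tie rule), and an
empty side warns.

## Multilevel condition model

Trial scores are modeled as
score_ij = γ0 + b0_i + (γ1 + b1_i)·SD_ij + ε_ij with (b0, b1) correlated
bivariate normal per participant, fit by REML (statsmodels MixedLM). The
outcome is internally scaled to unit variance and coefficients scaled back,
which makes results exactly invariant to the NNMF score scale and improves
optimizer conditioning; if the correlated fit fails (non-convergence or
non-finite standard errors) the model refits with independent random
effects, logged, and singular random-effects covariances are flagged.
t = B/SE with df = n_obs − n_groups − n_level1_slopes — the convention that
yields t(351) for 384 trials from 32 participants with one level-1 slope —
and the 95% CI is the Wald interval (labeled as such; profile intervals are
not computed). The standardised slope is B·sd(dummy)/sd(outcome) over all
trials; a within-person standardisation is a reasonable alternative but the
between+within pooled form is the default. The manipulation order
(SI-first/SD-first) can enter as a level-2 covariate; on data generated
without order effects its inclusion does not change conclusions (checked in
tests). With random-effects variance forced to zero the estimates reduce to
pooled OLS (limit asserted in tests); an R nlme fit of the same model is
used as an independent oracle in the test suite.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes, at
the study's design scale: 2 runs × 10 trials (6 negative / 4 neutral, never
more than two consecutive same-valence trials), announce 5 s, feedback 30 s
+ fixation 60 s (the 90 s epoch), self-paced instruction (8–12 s), drawing
(20–40 s) and relax (8–12 s) periods, TR 2.04 s — giving runs of ≈ 680
volumes, matching the average acquisition length. Defaults:

* loadings: explosiveness = gamma(shape 2, scale 6 s) shaped (peak ≈ 6 s,
  within the first third of the epoch); accumulation = (t/90)^1.5, smooth
  and monotone; both unit-norm on the 44-sample grid.
* scores: lognormal (σ_log = 0.5) with medians 500 (explosiveness) and 900
  (accumulation) drawing-device units; under self-distancing the location is
  multiplied by δ = 0.7 — distancing lowers both features by ~30%,
  a multiplicative effect respecting nonnegativity. These magnitudes put the
  raw condition slopes and their dispersion on the scale implied by
  standardised slopes near −0.3 with mean scores of a few hundred units.
* profile noise: truncated-at-zero Gaussian, SD 15 device units (~10% of
  signal RMS) — drawn intensities cannot be negative.
* BOLD: 24³ voxel grid (3 mm) by default with a spherical "brain";
  two disjoint planted spheres (radius 2.5 voxels) respond to the truth
  explosiveness and accumulation regressors with per-volume SNR amplitude
  0.5 (the planted time course is the HRF-convolved truth regressor scaled
  to amplitude × noise-SD per unit regressor SD; the implied coefficient
  maps are emitted for recovery tests); noise is AR(1) (φ = 0.3, stationary
  SD 1) plus per-voxel slow cosine drift (periods 150–400 s) and a small
  motion-coupled component driven by random-walk motion parameters.
  Between-subject amplitude jitter (SD 20%) makes the group analysis a true
  random-effects problem.

All generators are pure functions of (config, seed). What the generator
does **not** emulate: spatial autocorrelation (smoothness) of BOLD noise,
physiological (cardiac/respiratory) structure, realistic head motion,
nonlinear HRF variation across regions and subjects, drawing-motor artefacts
in the profiles, and any misspecification of the two-component model itself
(real profiles need not be exactly rank-2 plus noise). Passing tests
therefore show that the *pipeline* is correct and calibrated under its own
assumptions, not that those assumptions hold for any particular dataset —
the usual epistemic limit of simulation-based validation.

## Validation suite sizes

The study-level checks are sized for a single CPU: voxelwise calibration on
3 × 48³ null maps of 32 subjects; cluster-FWER calibration on 60 null
studies of 12 subjects on 14³ grids with 199 sign-flips each (a liberal
p < .01 / extent-3 forming rule so that clusters actually occur under the
null — the validity of the max-statistic correction does not depend on the
forming threshold); the double dissociation on 20 full studies of 10
participants on 18 × 18 × 14 grids with a 20-restart NNMF refit; and the
multilevel recovery on 200 replicates at the full 32 × 12 design. The
acceptance script runs the complete set in about two minutes.

## Known limitations

* OLS first level without AR(1) prewhitening (optional whitening was
  considered and deliberately left out; group inference is the target).
* No HRF temporal/dispersion derivatives; no small-volume correction; no
  atlas labeling or Talairach transform — peaks are reported in world mm.
* Whether the extent rule should keep clusters of exactly 10 is ambiguous
  in common reporting ("> 10" footnotes vs "extent 10" thresholds);
  ≥ k is used and configurable.
* The Bonferroni family for ROI tables is a parameter, not inferred.
* The multilevel CIs are Wald; REML is the criterion (the software-family
  default), not ML.
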