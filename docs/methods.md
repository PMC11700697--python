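# Methods

This note documents the models, parameter choices and numerical conventions
behind `pasa`, and what the synthetic study can and cannot say about real
measurements.

## Signal model and the synthetic generator

The generator emulates a two-arm in vivo study: 50 normal and 50 cancerous
tissue samples, each scanned at 51 laser wavelengths (1200–1700 nm, 10 nm
steps) with a 250 MHz digitizer. Per sample and wavelength it renders two
time series of 4096 points:

    sample(t)    = gain · energy(λ) · A(λ) · pulse(t) + ε(t)
    blackbody(t) = energy(λ) · a_bb · pulse(t) + ε(t)

with `A(λ) = Σ_i f_i μ_i(λ)` the composite of the chromophore volume
fractions `f_i` (collagen, water, lipid) weighted by normalized absorption
curves `μ_i`. The model is deliberately zero-dimensional: the photoacoustic
source is treated as a point absorber whose pressure amplitude is
proportional to absorbed optical energy. No acoustic propagation, transducer
geometry, or light transport is simulated, and there is no fluence–depth
correction; consequently the spectra carry no depth information and no
spectral coloring from overlying tissue.

**Absorption curves.** `μ_i` are Gaussian mixtures (parameters in
`src/pasa/data/absorption.yaml`), normalized to unit maximum on the grid.
They are coarse approximations of published NIR-II spectra — water peaking
near 1450 nm, lipid rising steeply toward its 1720–1730 nm band with a small
1210 nm bump, collagen broad with local maxima near 1350 and 1590 nm — not
literature-exact tables. The shapes were chosen once so that the pooled
fraction-weighted dominance pattern forms four contiguous segments
(collagen 1200–1390, water 1400–1520, collagen 1530–1640, lipid
1650–1700 nm), close to the canonical partition used for the published
feature-set composition. Ground truth for all recovery tests is this
internal dominance pattern, so the tests check internal consistency of the
pipeline, not fidelity to any particular tissue.

**Class-conditional composition.** Fractions are Gaussian with class
means/SDs (normal: collagen 0.34 ± 0.05, water 0.40 ± 0.07, lipid
0.18 ± 0.04; cancer: collagen 0.24 ± 0.08, water 0.40 ± 0.10, lipid
0.18 ± 0.06), clipped to [0.01, 0.95] and jointly rescaled if the sum
exceeds 0.98. Collagen and lipid share a latent factor giving correlation
0.3 (normal) and 0.7 (cancer). These encode the study's qualitative
structure — collagen-rich normal tissue, greater cancerous heterogeneity,
stronger collagen–lipid coupling in tumors — with effect sizes chosen for
testability; no quantitative effect sizes are available to calibrate to.

**Nuisance terms.** Pulse energy follows a smooth wavelength profile times a
lognormal per-shot jitter (log-SD 0.10) shared exactly between the two
channels, which is what makes blackbody calibration cancel it. A per-sample
lognormal coupling gain (log-SD 0.01 normal, 0.03 cancer) models
tissue–transducer coupling variability; it is kept small so that spectral
shape, not coupling, dominates the between-sample variance — with large
gain variability, any cross-band wavelength pair becomes a useful
gain-cancelling ratio and the distinction between informative and
uninformative wavebands that the selection stage is meant to recover
disappears. White noise (SD 0.005 in trace units) is added to both
channels. The three random streams (composition, energy, noise) are split
from the per-sample seed, so disabling one leaves the others bit-identical.

**Pulse.** A Gaussian-modulated sinusoid centered at 2.5 MHz with fractional
bandwidth 0.8, placing most pulse energy inside the 1–4 MHz analysis band
(the band above which real signals are strongly attenuated). The sample
channel is additionally shaped by a packaged hydrophone sensitivity curve
(0.55 + 0.45·exp(−(f−3)²/8), strictly positive), which the processing stage
compensates.

## Spectral processing

Both channels receive a zero-phase 4th-order Butterworth 1 MHz high-pass
(effective 8th order through forward–backward filtering; DC rejection
> 40 dB well below cutoff, passband ripple < 1 dB above 2 MHz). Peak-to-peak
calibration is applied after filtering on both channels — the acquisition
order is not otherwise determined, and filtering first makes the reference
amplitude insensitive to low-frequency drift; this is configurable in
principle by calling the steps directly. Welch PSDs use a Hamming window of
1/8 the trace length with 50% overlap, a standard variance/bias compromise;
hydrophone compensation divides the PSD by the squared sensitivity (power
domain). APSD is the trapezoidal integral over 1–4 MHz with
linearly-interpolated band edges, making the quadrature error second order
in the frequency step. Degenerate inputs fail loudly: a blackbody
peak-to-peak below 1e-9 (configurable) raises an error naming the
wavelength, as do band edges outside the PSD grid.

## Unsupervised characterization

Wavelength profiles are z-scored per wavelength (n−1 denominator; constant
columns are an error) and clustered agglomeratively under Euclidean
distance. Complete linkage is the default, matching the convention of the
clustering-heat-map tooling common in this literature; single/average/ward
are available. The tree is cut at k = 3 and each cluster takes the
chromophore with maximal mean normalized absorption over its wavelengths,
ties broken toward collagen. The partition is computed on the full
100-sample matrix by default (a per-class subset can be passed instead);
collagen may legitimately own two disjoint segments.

Spearman matrices use tie-corrected average ranks. The wavelength network
has an edge where SCC strictly exceeds τ = 0.9 ("surpassed" is read as
strict); thresholding is plain and elementwise, with no contiguity
constraint. WalkTrap runs with the canonical step length 4 and is cut at
the modularity-maximizing level; isolated nodes become singletons and
community ids are ordered by descending size. Betweenness is normalized by
(n−1)(n−2)/2 so a star center scores exactly 1. The PCA baseline retains
components with eigenvalue > 1 on the z-scored matrix.

## GA wavelength selection

Fitness is RMSECV of an intercept-plus-least-squares regression of the 0/1
response on the included APSD columns, under 5-fold class-stratified splits
drawn once per replicate run from the run's seed (so every individual in a
run is scored on identical folds). The least-squares solve uses SVD and
therefore degrades to the pseudo-inverse solution under rank deficiency.
Defaults: population 64, initial inclusion probability 0.15 (mean subset
size ≈ 8, the regime of the published best model), 50 generations, 100
replicate runs, per-bit mutation 0.005. Selection removes individuals with
RMSECV strictly above the median; survivors are paired at random and bred
by two-point crossover ("double crossover" read in its standard GA sense);
empty offspring are repaired with one random wavelength.

The retention rule is an interpretation, since no rule reproducing a fixed
model count per run is derivable: the run's incumbent starts at the
all-wavelength RMSECV on the run's folds and every generation best that
strictly improves the incumbent is retained. A run therefore contributes a
handful of models and the collection grows to the order of a few hundred
per hundred runs. Inclusion frequency is the fraction of retained models
containing each wavelength; the global best model defines the feature
wavelengths.

A note on the null behaviour: against a *fixed* dataset with permuted
labels the GA still concentrates on whichever columns are spuriously
correlated in that sample, so inclusion frequencies are only approximately
uniform when the permutation is redrawn per replicate — that is how the
no-systematic-preference property is tested.

## Classification

All models are validated on a seeded stratified 10-fold plan (5 + 5 test
samples per fold at n = 100). Per-fold calibration and testing metrics are
averaged; the confusion matrix and ROC/AUC are pooled over test predictions
(each sample tested exactly once), which is markedly more stable than
per-fold ROC at this sample size. Scores for the ROC are the cancer vote
fraction (KNN), the regression value (PLSDA) and the signed margin (SVMDA).

- **KNN**: Euclidean majority vote, K = 3 by default (odd, 3–9 enforced);
  distance ties break deterministically toward the lower training index.
- **PLSDA**: PLS1 regression of the 0/1 response; the number of latent
  variables is the count of principal components of the column-standardized
  predictors with eigenvalue > 1 (Kaiser-style reading of the LV rule),
  at least 1. The decision threshold is the equal-likelihood crossing of
  class-conditional Gaussians fitted to training scores, falling back to
  the midpoint when variances are within 1e-6 relative (the crossing is
  ill-conditioned and degenerates to the midpoint there anyway). Training
  folds are screened iteratively for samples exceeding **both** the
  Hotelling-T² (F-distribution) and Q-residual (Jackson–Mudholkar) 99%
  limits — "both" is the stricter reading of the joint condition, with
  "either" available; screening stops rather than reduce any class below
  3 samples. Because the latent subspace follows the data, a gross outlier
  confined to few directions is typically absorbed into the model and
  flagged by T² alone; joint exceedance requires displacement both along
  and off the retained subspace.
- **SVMDA**: RBF kernel on autoscaled predictors (train-fold mean/SD —
  the usual preprocessing for spectroscopic discriminant analysis, and
  necessary for the absolute c/γ grid to be meaningful against APSD
  magnitudes of order 1e-4). The grid spans 10⁻⁶–10⁹, 16 log-uniform
  points per axis, scored by misclassification fraction under an inner
  stratified 5-fold CV inside each calibration fold (nested, so the outer
  test fold never leaks into model selection); ties prefer smaller c, then
  smaller γ. libsvm iterations are capped at 3000 to bound degenerate grid
  corners (e.g. enormous c with a near-constant kernel); winning pairs
  converge far below the cap.

## Pipeline

A single master seed derives one sub-seed per stage through
`SeedSequence.generate_state`, so stages are reproducible in isolation and
two runs with the same configuration are byte-identical. Each stage writes
a manifest (stage seed, configuration hash, output checksums); on resume a
stage re-runs only if its manifest or outputs changed. Configuration is
YAML with every default explicit and unknown keys rejected.

## Problem sizes and what the tests show

The packaged study conditions are 50 + 50 samples, 4096-point traces and
the full GA budget (100 × 50). The test suite and the acceptance script
exercise recovery at a reduced GA budget of 20 runs × 30 generations,
which is ample for convergence on this problem while keeping repeated
whole-pipeline runs cheap; the feature-vs-full-range classifier comparison
is averaged over 10 independently generated studies.

Passing tests demonstrate that the pipeline recovers structure *that the
generator planted*: the dominance partition, the collagen-band
concentration of GA selections, class separability, and the directional
advantage of feature-wavelength spectra. They do not validate the
generator against real tissue: real APSD spectra include depth-dependent
fluence coloring, acoustic attenuation and transducer diffraction, inter-
subject biology far richer than three fractions and a gain, and absorption
spectra that differ from the packaged Gaussian mixtures. Real-data
classifier metrics are therefore out of reach by construction, and the
published performance table enters only through metric-formula consistency
checks on its implied confusion counts.

## Known limitations

- The generator's APSD is flat in frequency apart from the pulse spectrum;
  structure-dependent ultrasonic spectral slope (a quantity of interest in
  PASA more broadly) is not modelled.
- The Kaiser eigenvalue rule ties PLSDA model order to the predictor
  correlation structure; on feature subsets with few, highly correlated
  columns it usually selects 1–2 LVs.
- WalkTrap at the modularity-optimal cut can split or merge communities
  differently from the fixed-level cut for near-degenerate networks;
  community ids are size-ordered, not stable across perturbations.
- The Q/T² screen re-fits after removing one sample at a time (worst
  offender first) up to 10 iterations; pathological configurations with
  many simultaneous outliers may hit the cap.
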