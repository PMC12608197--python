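# Methods

This note documents the models, algorithms and numerical choices behind
`leafspec`, and what the synthetic-data studies do and do not demonstrate.

## Data model and instrument conventions

The imaging unit is a push-broom VNIR cube (H × W × B reflectance) on a
uniform wavelength grid: 856 bands, 380 + 0.727·k nm. Quantitative modeling
uses the stable 430–900 nm window. The inclusive crop of the nominal grid
holds 647 channels; the window's definitional count is 646, obtained by
dropping the topmost channel (430.163–899.078 nm). All selected-wavelength
percentages are relative to these 646 channels; `crop_window` therefore
accepts an optional channel budget and `crop_modeling_window` applies
(430, 900, 646) canonically, while a plain inclusive crop remains the
identity when the window covers the grid.

Radiometric calibration is elementwise `(raw − dark) / (white − dark)`; a
zero white–dark difference is an error naming the offending pixel and band.
Per-column line references are expanded to full frames by spatial averaging
before calibration. ENVI I/O uses BIL interleave, float32, wavelengths in
the header — the most portable hyperspectral dialect. Pixels are 0-based,
row-major, origin top-left.

## Preprocessing

All steps are per-spectrum, so sample order commutes with the pipeline.

* **Savitzky–Golay** smoothing: local least-squares polynomial refit,
  polynomial order 1, window length 5, edges by polynomial extrapolation of
  the terminal windows. Instrument-software descriptions of this filter
  sometimes name both a "frame length" and a "window size"; a length-3
  window with an order-1 polynomial is nearly information-free, so the
  window length is 5 and the extra frame parameter is treated as a
  tooling artifact of FIR filter design.
* **SNV**: `(x − mean)/sd` with the sample (n−1) SD; exact mean 0 / SD 1
  per spectrum, idempotent, affine-invariant. Undefined (error) for a
  constant spectrum.
* **Detrending**: subtraction of the global least-squares polynomial
  baseline, default order 2, computed by projection onto an orthonormalized
  polynomial basis for numerical stability at any order. Detrending here is
  baseline-drift removal, not differentiation: derivative-style parameters
  that sometimes accompany "detrend" in acquisition software are not
  implemented.

Default order: S–G → SNV → DT. Note one interaction that matters for
synthetic studies: when the analyte signal is purely multiplicative in a
fixed band profile (as in the generator), SNV divides it away almost
entirely. Real spectra carry shape changes and scatter that SNV targets;
the generator's signal model does not. The selection and recovery studies
therefore preprocess with smoothing only, while SNV and DT are fully
implemented and tested as operations.

## SPXY partitioning

Joint distance `d = d_x/max d_x + d_y/max d_y` (Euclidean in X, absolute
difference in y), Kennard–Stone farthest-point selection starting from the
maximal pair, ties broken toward the lowest index, calibration size
`floor(n·ratio/(ratio+1))` — 551/184 at n = 735, ratio 3:1. The procedure
is fully deterministic. It is run per analyte: two analytes measured on the
same samples may receive different memberships.

## PLSR core

Single-response SIMPLS on mean-centered data (no unit-variance scaling —
preprocessing handles scale; centering-only is the chemometrics default).
The implementation returns the full coefficient path, so one decomposition
per training fold yields RMSE_CV for every latent-variable count at once —
the property that makes model-population selection (thousands of sub-model
evaluations) affordable. scikit-learn's NIPALS implementation agrees with
this SIMPLS to ~1e−9 on the coefficients for a single response and serves
as the independent cross-check in the tests, never as the implementation.

Cross-validation uses contiguous blocks of one seeded permutation; the
latent-variable count is the first minimum of RMSE_CV, capped globally at
10. Sub-model scoring inside all selectors uses a fixed fold assignment
(`cv_seed`, default 0) decoupled from the search randomness, so RMSE_CV is
a pure function of the channel subset: reported best values can be
recomputed exactly by an independent fold loop, and subsets found by
different searches are comparable.

Metrics: R is the Pearson correlation between predictions and references
(NaN for a constant prediction), RMSE = √(Σ(ŷ−y)²/n), and
RPD = SD(y, n−1)/RMSE (∞ for a perfect fit). RPD is defined this way
unconditionally rather than reverse-engineered from any published table.

## The selection cascade

Twelve strategies = {iRF, iVISSA} × {CARS, BOSS, VCPA} × {IRIV, GA}. Every
stage sees calibration rows only; prediction rows are touched solely by the
final evaluation (shuffling prediction responses changes no selection and
no calibration metric — tested). Each stage returns a sorted, unique
channel subset that is enforced to be contained in its parent's.

### Coarse stage

**iRF** (interval random frog): the search state is a set of contiguous
10-channel intervals, initialized as 20 equidistant windows; proposals add,
remove or shift one interval and are accepted when
`RMSE_CV · (1 + 0.6·k/p)` is within an annealed tolerance (0.005 → 0) of
the current score. The multiplicative size penalty supplies the restoring
force that sheds intervals contributing nothing — without it the null
intervals random-walk. Channel frequencies are accumulated after a 30 %
burn-in, and channels present in ≥ 50 % of the counted states are selected.
Despite the conventional "random forest" expansion of the acronym, the
configuration that defines this selector (moving window, equidistant
subintervals, a PLS latent-variable cap) describes an interval
random-frog-style search over PLSR sub-models, and that is what is
implemented.

**iVISSA** (interval variable iterative space shrinkage): weights live on
contiguous 10-channel intervals (it is an *interval* method; per-channel
weights cannot separate redundant channels inside one absorption band).
Sub-models are unions of intervals drawn with probabilities rescaled to a
sparse budget (10 % of intervals — sparsity is what makes enrichment
informative). Each interval's lift — frequency in the best 10 % of
sub-models over its overall frequency — relative to the weight-averaged
mean lift multiplies its weight (power 1.5, capped at 1); intervals
enriched above average grow toward 1, the rest decay toward 0, and
adjacent-interval smoothing ([0.25, 0.5, 0.25]) grows contiguous
selections. Iteration stops at max |Δw| < 0.01 or 15 rounds; intervals
with w > 0.5 are selected. The 0.01 tolerance and 10 % best-fraction
follow the method family's originating literature and are exposed as
configuration.

### Fine stage

**CARS**: per Monte Carlo run, PLSR on a random 80 % row subset ranks
channels by |coefficient|; the exponentially decreasing function
`r_i = a·e^(−k·i)` with boundary conditions r₁ = 1 and r_N = 2/p₁ (hence
k = ln(p₁/2)/(N−1), a = e^k) forces the retained count from p₁ down to 2,
followed by adaptive reweighted sampling among the survivors. Each run's
subset is scored by RMSE_CV on all calibration rows; the minimal run wins.
The 80 % row fraction is the conventional default.

**BOSS**: rounds of weighted bootstrap channel sampling (p draws with
replacement per sub-model); the best 10 % of sub-models contribute their
normalized |coefficient| mass to the next weight vector (soft shrinkage —
weights decay smoothly, summing to 1 each round, and a channel dies only
when its mass underflows). Rounds stop when the weight support stops
shrinking; the overall minimum-RMSE_CV sub-model is returned.

**VCPA**: a geometric pool schedule shrinks the candidate pool to 100
variables over 50 EDF iterations; each iteration draws 1000 random binary
combinations at a fixed 10 % inclusion ratio, and the channels most
frequent in the best 10 % survive. The final subset search runs over
nested prefixes of the frequency ranking (sizes 2..30) with a greedy drop
refinement; a literal exhaustive pair/triple search over a 100-variable
pool would cost > 160 000 cross-validated fits and buys nothing on these
problems, so the nested-prefix search is the deliberate desk-scale design.

### Optimal stage

**IRIV**: per round, a random binary inclusion matrix (500 sub-models,
inclusion probability 0.5) yields an RMSE_CV population; for channel i,
`DMEAN_i = mean(RMSE_CV | included) − mean(RMSE_CV | excluded)`, so
informative channels have DMEAN < 0, and a two-sided Mann–Whitney U test
at α = 0.05 splits strong (p < 0.05) from weak informative channels and
interfering (p < 0.05) from merely uninformative ones. Uninformative and
interfering channels are dropped; rounds repeat until only informative
channels remain (a pair is the smallest assessable model and is kept);
finally weak channels are removed one at a time, least informative first,
whenever removal lowers RMSE_CV. The final subset contains no channel with
DMEAN > 0 in its last assessment.

**GA**: 30 binary chromosomes capped at 30 set bits (repair by random bit
clearing; an empty chromosome gets one random bit), fitness −RMSE_CV,
tournament selection of size 2, single-point crossover at probability 0.5,
per-bit mutation at 0.01, elitism (the best-ever chromosome always
survives, making best fitness non-decreasing), and a hard budget of 200
subset evaluations — read literally as an evaluation budget (≈ 7
generations), not a generation count.

### Cascade bookkeeping

A PLSR model is refit at every stage boundary with its own CV-selected
latent-variable count. The comparison table reports NV, NV as a percent of
the 646-channel window (2 decimals), and R/RMSE/RPD for calibration and
prediction per stage; the best strategy is flagged by maximal prediction R,
ties broken by minimal prediction RMSE. Wavelength reports print
nearest-integer nm labels while indices stay exact internally.

## Pixel-wise inversion and mapping

A pixel's full-window spectrum is preprocessed exactly like the tabular
spectra, then the model's channel subset is dotted with the coefficients —
so a pixel whose spectrum equals a calibration sample's mean spectrum
reproduces the tabular prediction to 1e−10 (tested). Background pixels
carry NaN. The enhanced Lee filter classifies each 3×3 window by its
coefficient of variation C = sd/|mean| (sample SD, background excluded):
C ≤ 0.52 → local mean; C ≥ 1.73 → pixel preserved; otherwise
`mean + w·(x − mean)` with `w = exp(−damping·(C − 0.52)/(1.73 − C))` — a
convex blend, so no output leaves its window's [min, max]. Filtering acts
on the float concentration values (lossless), not on a quantized grayscale
image. Rendering maps the display range (nitrogen [0, 7.64] %, chlorophyll
[0, 3.70] mg/g by default) onto a monotone blue→cyan→green→yellow→orange→
red colormap with pure blue/red endpoints; stored values are not clipped,
only the display is.

## The synthetic-data generator

`simulate_spectra` draws responses uniformly over the analyte range
(nitrogen 0.7374–7.6357 %, chlorophyll 0.2614–3.7026 mg/g) and builds
reflectance as `baseline − Σ effect_j · y · G(center_j, width_j) + noise`,
clipped to [0, 1]. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| planted bands | 479, 689 nm; width 15 nm; effect 0.03 per unit | shared blue/red diagnostic wavelengths; broad pigment features |
| baseline | 0.55 reflectance | leaf-like VIS/NIR plateau |
| detector noise | SD 0.005 (i.i.d. per channel) | benchtop SNR |
| baseline drift | SD 0.003, 30 nm correlation length, per sample | smooth illumination/scattering drift — the component detrending targets |
| reference-assay error | SD = 5 % of the analyte range, clipped at 0 | wet-chemistry uncertainty; without it every model is near-perfect and percentage comparisons between models become meaningless |

Gaussian (not Lorentzian) profiles are the simplest shape matching broad
pigment absorptions. Uniform responses match a published min/max range
without assuming an unprinted distribution, so simulated summary SDs are
only approximate analogues of measured ones. The drift term is what makes
two distant bands complementary (averaging independent local drift) and
the i.i.d. term what rewards covering a whole band — without either, a
single channel per band is information-complete and no selector can be
expected to retain full bands.

`two_block_config` defines the recovery-study conditions: bands narrowed to
3.6 nm (signal confined to ~10 channels each), effect 0.05, detector noise
0.02, drift 0.01, and *exact* reference values — the recovery study
isolates spectral noise from assay error, because assay error at realistic
amplitude makes sub-model CV differences at n = 200 smaller than the CV
noise floor and measures the sample size, not the selector.

`simulate_cube` paints an elliptical leaf (background at a flat 0.02
reflectance, making segmentation trivially testable) with a smooth
tip-to-base concentration gradient depressed on a main vein, straight
secondary veins, and the leaf base, and returns the true field for
recovery tests.

What passing these studies shows: the selectors retain planted informative
channels and discard unrelated ones under realistic noise; the cascade
preserves full-spectrum accuracy while removing ~99 % of channels; the
pixel path is algebraically identical to the tabular path. What it does
not show: performance on real leaf spectra, whose scatter, water bands,
nonlinear pigment saturation and structural covariance the generator does
not emulate (no radiative-transfer realism, by design).

## Problem sizes and budgets

Sampling-based selectors default to their reference configuration (1000
iRF iterations, 1000 iVISSA/BOSS/VCPA sub-models, 100 CARS runs, 50 VCPA
EDF iterations, 500 IRIV sub-models, 200 GA evaluations).
`CascadeConfig.reduced()` scales the sampled populations down (e.g. 100
sub-models, 5-fold sub-model CV) for desk-scale runs; the shipped test
suite and examples use these reduced budgets with the full 735-sample ×
646-channel fixture, which completes the twelve-strategy cascade in well
under a minute on one core. Budgets change sampling density, never the
algorithms.

## Known limitations

* iRF's greedy accept/reject chases cross-validation noise when the
  irreducible error floor is large relative to subset differences; with
  small samples it may keep a sliver of a broad band. The interval-wise
  iVISSA is markedly more stable in that regime.
* The iVISSA weight update (relative-lift competition with a cap) is this
  package's concrete realization of "iterative space shrinkage"; the
  originating description leaves the update underdetermined.
* SPXY is O(n²) in memory (joint distance matrix) — fine for thousands of
  samples, not for pixel populations.
* Pseudocolor rendering embeds no spatial calibration; maps are
  pixel-space only.
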