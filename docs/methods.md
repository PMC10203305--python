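# Methods

This note documents the models and procedures implemented in `cinetrf`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions taken where the design was open.

## Signal model and TRF estimation

BHA in each channel is modelled as the output of a linear time-invariant
system driven by named regressors on a shared 60 Hz clock — impulse trains
(film cuts, event/continuous cuts, saccade onsets, novelty- or face-split
saccade subsets) and continuous series (optic-flow motion).  Kernels span
lags −0.5 … +3 s (211 lags at 60 Hz) and are estimated per channel by ridge
regression on the time-lagged (Toeplitz) design, jointly over all selected
regressors so that temporally coupled inputs (saccades cluster after cuts;
motion rises before saccades) do not contaminate one another's kernels.

Numerical conventions, each of which changes results and is therefore fixed
and recorded:

- **Ridge scaling.** The solve is `(XᵀX + λ·m·I) w = Xᵀy` with `m` the mean
  diagonal of `XᵀX`, making λ = 0.3 dimensionless (the common convention of
  TRF toolboxes).  A raw `λ·I` variant is available via `scaling="raw"`.
- **Regressor standardization.** Continuous regressors are z-scored and
  *all* regressors are then scaled to unit RMS before the solve; kernels
  are reported in original units per regressor unit by back-scaling.
  Without this, the design block of a continuous regressor dominates `m`
  and the penalty flattens the kernels of sparse impulse trains — with
  unit-RMS blocks λ shrinks every regressor equally and λ = 0.3 behaves as
  intended.  This is the package's choice where conventions differ across
  toolboxes; it changes kernel units only through the recorded scales.
- **Intercept handling.** Design columns and BHA are mean-centered together
  (the exact equivalent of an unpenalized intercept).  Centering only the
  output leaves a constant the lagged design cannot represent and biases
  even noiseless estimates.
- **Edges and masks.** Lagged columns are zero-padded at the recording
  edges.  Artifact-masked samples are excluded from the regression through
  a sample-weight vector (weight 0 drops the row); they are never
  interpolated, which would fabricate data.
- **Smoothing.** Estimated kernels are convolved along lag with a unit-area
  Gaussian of σ = 53 ms (≈3.2 samples), reflect-padded, preserving the lag
  integral; smoothing is refused twice unless forced.
- **Event amplitudes.** The per-event scaling β = ⟨w, y_window⟩/⟨w, w⟩ is
  exact scalar least squares.  When the TRF itself was fit with a large
  ridge, β is inflated by the common inverse shrinkage factor (≈1.3 at
  λ = 0.3 with unit-RMS blocks); condition contrasts (event vs continuous,
  high vs low novelty) are unaffected because the factor cancels, and the
  self-consistency property β̄ ≈ 1 holds at small λ.

## Cluster-permutation statistics

Surrogate BHA is built by circular shifts: one uniform offset per electrode
per surrogate (margin 5% of the recording length at both ends, to exclude
near-identity shifts), applied jointly to all channels of the electrode so
their covariance is preserved; regressors stay fixed and TRFs are refit
with the identical design and λ.  When no samples are masked, the refit for
every offset is obtained from a single FFT cross-correlation pass per
channel, which makes hundreds of surrogates cheap; with masks, each
surrogate is refit directly.

The pointwise statistic is two-sided, `α = (1 + #{|surr| ≥ |obs|})/(1 + n)`
(add-one, never exactly zero).  Supra-threshold points form clusters under
"adjacent lags on one channel ∨ adjacent channels (shaft chain or grid
4-neighbourhood) at one lag", per regressor; the cluster weight is the
summed squared kernel.  The null for a cluster is the distribution over
surrogates of the maximal surrogate cluster weight on its electrode (each
surrogate's supra-threshold set obtained by ranking it within the full
ensemble).  Raw p-values from all clusters — across electrodes, regressors
and recordings — are pooled into one Benjamini–Hochberg correction at
q = 0.05.

**Scaled runs.** The add-one α cannot fall below 1/(n_surr+1), so the
full-scale forming threshold α < 0.001 is attainable only for
n_surr ≥ 1000.  Desk-scale analyses here use n_surr = 500 with
α_forming = 0.005 (a point must be more extreme than at most one
surrogate); false-positive control does not depend on the forming threshold
because the cluster-mass null absorbs it.  Calibration at this scale
(20 synthetic patients × 20 pure-noise channels) flags ≈0% of channels,
and a planted 300 ms kernel at SNR 1 in half the channels is detected with
sensitivity 1.0 (see `tests/test_acceptance.py`).

## Saccade detection

Positions are median-filtered (20-sample window, output aligned
`[i−10, i+9]`, the convention of common even-order median filters), speed
is the magnitude of central differences in DVA/s, and the threshold is
mean + 2 SD of speed over valid samples, computed per recording.
Supra-threshold runs are closed with a 5-sample structuring element to
merge the post-saccadic overshoot.  Onset is the first marked sample;
fixation onset is the first later sample below the 70th percentile of
speed within [onset − 33 ms, onset + 120 ms] (pooled per saccade, as the
rule is stated).  Exclusions apply in order: within 83 ms of an invalid
sample, then within 110 ms of the previous retained onset.  The 2-SD rule
uses scalar speed (not per-component velocity), making the detector
translation-invariant and scale-covariant.

## Event segmentation

Rater presses are shifted back 1 s (reaction correction, clipped at 0),
aggregated as impulses at 60 Hz, and smoothed with a unit-area Gaussian of
σ = 0.5 s truncated at 4σ; salience is then in raters/s and the curve
integrates to the press count.  Per movie, cut saliences are split by the
two-segment change point minimizing total within-segment squared error
(exact, via prefix sums; verified against exhaustive search); cuts at or
above the threshold are event cuts.  The matched continuous set starts
from the equally many lowest-salience cuts and is resampled from the
lower-salience half until no feature's |Δ| differs (Wilcoxon signed-rank
after pairing cuts by salience rank — the rank-sum variant is available,
since the pairing underlying the published signed-rank use is not
documented), BH-corrected across features only.

## Saccade semantics

Novelty is the Euclidean distance between pluggable feature vectors of the
pre- and post-saccadic foveal patch.  Saccades spanning a cut or starting
within 1 s after one are excluded; a least-squares line novelty ~ amplitude
divides the rest by residual sign, and exact equal group sizes are enforced
by moving the smallest-|residual| saccades across the boundary (ties by
onset time) — the minimal-distortion completion of "matched in number".
Face-saccade features f1–f5 are computed in degrees visual angle from the
fixation-frame boxes (the features describe the landing target); the
5-DVA disc overlap uses a fixed 115×115 sampling grid (>10⁴ points inside
the disc, within 0.01 of quadrature).  The default classifier is a
Gaussian-kernel SVM with kernel scale 2.2 (γ = 1/2.2²) on standardized
features; scores < 0 are non-face, > 1 face, and the undefined middle
[0, 1] is excluded as the conservative completion of the two stated
regions.  Trained weights are never shipped.

## Specificity and parcel maps

`S = 1 − N12/(N1+N2)` is implemented exactly as the defining equation; note
it is not literally one minus the Jaccard index (full overlap gives
S = 0.5, not 0), so its effective range is [0.5, 1].  Because
T = N1+N2−N12 identically, no permutation can preserve all three counts;
the null reassigns each of the T responsive channels uniformly to
{condition 1, condition 2, both} (the natural reading of randomly
reassigning responsiveness), with an independent-subsets variant
(hypergeometric overlap, conditioning on N1 and N2) behind `null=`.  The
region statistic is the median S across patients; p-values use the add-one
convention with ≥-ties, are BH-corrected across regions, and regions where
any patient contributed exactly one responsive channel are excluded (no
distinct permutations exist).  Ties on the discrete S grid make the test
conservative for homogeneous channel counts; the null-calibration study
therefore uses heterogeneous counts (14 patients, 10–40 responsive
channels), where the measured p-distribution is uniform to KS ≈ 0.03–0.05
over 500 runs — the residual being jointly KS sampling noise
(≈1.36/√500 ≈ 0.06 at the 5% point) and tie mass.

Parcel projection weights each electrode by `exp(−4·ln2·d²/FWHM²)` with
FWHM = 4 mm (weight 0.5 at 2 mm), restricted to electrodes within 4 mm;
a parcel is excluded when its highest single-electrode weight is below 0.5
(the max-weight reading of the exclusion rule; a summed-weight variant
would exclude less).  Gradient comparisons use Spearman correlation over
non-excluded parcels, treating coarse parcels as independent.

## Synthetic data: what it emulates, and what it does not

The generators produce every pipeline input with recorded ground truth and
an explicit seed (identical seeds ⇒ bitwise-identical outputs; a JSON
manifest logs all parameters):

- **Gaze** (300 Hz): minimum-jerk position ramps at renewal times with a
  150 ms refractory gap, Gaussian fixation tremor, optional blink-like
  invalid spans.  Defaults: 2 saccades/s, amplitudes 4–12 DVA, durations
  18 ms + 0.8 ms/DVA.  The ramp is sampled so its first in-flight sample
  sits at the labelled onset, matching the detector's "first sample in the
  saccade" convention; the brisk durations keep the velocity-threshold
  crossing within the 2-sample tolerance the recovery tests use.
- **Stimulus**: cut times uniform with ≥2 s spacing; per-cut true salience
  from a bimodal profile (so change-point classification has signal);
  positive AR(1) motion (φ = 0.9, i.e. ≈0.16 s time constant — sub-second
  optic-flow fluctuation; much smoother motion would make its kernel
  unidentifiable in principle); per-frame features stepping at cuts.
- **Annotations**: per-rater presses = boundary + truncated-normal reaction
  delay (mean 1 s, SD 0.3 s), independent misses, optional Poisson false
  presses.
- **Regressor couplings**: saccade rate dips then rebounds after cuts, and
  motion ramps up before saccades.  The windows and gains are parameters —
  the couplings observed in film data are empirical and no particular
  generative law is treated as ground truth.
- **BHA**: kernel convolutions plus white or AR(1) noise; null channels
  have zero kernels; channels are laid out on synthetic shafts with chain
  adjacency and cycling region labels.
- **Patch features**: pre/post vectors whose distance is exactly
  slope·amplitude + effect·z + noise with exactly balanced hidden labels z
  (mirroring the equal-sized groups the analysis forms).

Passing tests on these data show that the estimators and statistics are
correct and calibrated under the stated models.  They do not show
robustness to everything real recordings contain: 1/f spectra and
nonstationarity of BHA, smooth pursuit and microsaccades in gaze,
tracker-specific quality codes, smooth film transitions (undetectable by
temporal contrast, as in the original workflow, where they were corrected
by eye), or nonlinear/interaction responses (outside the linear model by
construction).  AR(1) noise probes — but does not exhaust — the
sensitivity of circular-shift nulls to temporal autocorrelation.

## Problem sizes in the tests

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each property is meaningfully exercised: 40 min of
60 Hz data for parameter recovery; 20 synthetic patients × 20 channels ×
5 min with 500 surrogates for cluster calibration; 10 min of gaze for
detector accuracy; 500 runs × 200 permutations for the specificity null;
1000 sequences for the change-point oracle; 10⁴ random lists for the BH
equivalence check.

## Known limitations

- Electrode localization, optical-flow computation, CNN feature extraction
  and face-detector training are out of scope; the pipeline consumes their
  outputs through pluggable interfaces.
- The surrogate ensemble is held in memory (float32, channels × regressors
  × lags × n_surr); at 10⁴ surrogates and hundreds of channels this
  requires analysing recordings one at a time or extending the code to
  stream blocks.
- Group-level models (mixed-design ANOVA, Skillings–Mack) are not
  reimplemented; the package emits tidy per-event and per-region tables
  that make them one-liners in standard statistics software.
- `classify_cuts` with a single cut per movie, or identical saliences,
  leaves cuts unclassified (degenerate change point) rather than guessing.
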