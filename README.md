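# cinetrf

Temporal response functions and cluster statistics for intracranial
responses to visual change during film viewing.

## The problem

When people watch movies, abrupt visual changes arrive through two routes:
the film's own editing (cuts between shots) and the viewer's eye movements
(saccades, which replace the foveal image several times per second).  Both
kinds of change drive transient responses in the broadband high-frequency
amplitude (BHA, the 70–150 Hz envelope of an intracranial channel, a proxy
for local neuronal firing).  This package estimates those responses, tests
where they are statistically reliable, and asks how they depend on the
*meaning* of the change: does a cut end a narrative event, does a saccade
land on something novel, does it land on a face?

It is written for electrophysiologists analysing intracranial recordings
made during naturalistic viewing, together with gaze traces and stimulus
annotations — and for anyone who wants a fully tested, simulation-backed
reference implementation of this analysis style.

## The model

Each channel's BHA is treated as the output of a linear time-invariant
system driven by stimulus/behaviour time series co-sampled at 60 Hz:

```
y_c(t) = Σ_r Σ_ℓ  w_cr(ℓ) · x_r(t − ℓ)  +  ε(t)
```

The kernels `w_cr(ℓ)` — temporal response functions (TRFs) — span lags from
0.5 s before to 3 s after the stimulus sample (211 lags) and are estimated
jointly for all regressors per channel by ridge regression (dimensionless
λ = 0.3, scaled by the mean diagonal of `XᵀX`), which deconfounds
temporally correlated inputs such as the saccade bursts that follow cuts.
Estimated TRFs are smoothed along lag with a Gaussian (σ = 53 ms).

Significance is assessed with circular-shift surrogates: the BHA of each
electrode is circularly shifted in time (inputs untouched), TRFs are refit,
and supra-threshold points (pointwise α < 0.001 at full scale) are grouped
into clusters over adjacent lags and spatially adjacent channels.  Cluster
weights (summed squared TRF amplitude) are compared with per-electrode
maxima of surrogate cluster weights, and p-values are pooled and corrected
by Benjamini–Hochberg FDR at q = 0.05.

Around the model sit the pipeline stages: raw signal → BHA preprocessing,
saccade detection from gaze, film-cut detection, rater-based event
salience and event/continuous cut classification, saccade novelty and
face-target labelling, per-event response amplitudes, response specificity
`S = 1 − N12/(N1+N2)` with a permutation null, and Gaussian-weighted
projection of channel results onto cortical parcels.  A synthetic-data
module generates every input with known ground truth, so the entire
pipeline is testable without patient recordings.

## Worked example

```python
import numpy as np
from cinetrf import synthetic
from cinetrf.trf import TRFModel

# a synthetic 10-minute session: coupled cut/saccade/motion regressors,
# known kernels in 10 channels, white noise at amplitude 1
reg, events = synthetic.generate_regressor_set(600.0, seed=0)
kernels = synthetic.random_kernels(10, 3, seed=1)
bha, info, truth = synthetic.generate_bha(reg, kernels, noise_sd=1.0, seed=2)

model = TRFModel(bha.envelope, reg, channel_info=info)
res = model.fit(ridge=0.3).smooth()
print(res.summary())
```

```
Temporal response function model
================================================
channels:        10
regressors:      cuts, saccades, motion
samples:         36000 at 60 Hz
lag window:      -0.500 ... +3.000 s (211 lags)
ridge lambda:    0.3 (mean_diag)
smoothing:       sigma=53 ms
  |TRF| peak cuts                   median 1.4  max 2.64
  |TRF| peak saccades               median 0.781  max 1.86
  |TRF| peak motion                 median 0.452  max 0.954
```

The kernel peaks are in BHA amplitude units per event (impulse regressors)
or per standard deviation of motion.  Comparing with the generator's
ground truth and testing significance:

```python
r = np.mean([np.corrcoef(res.kernels[c, j], kernels[c, j])[0, 1]
             for c in range(10) for j in range(3)])
print(f"mean correlation with ground-truth kernels: {r:.3f}")
sig = res.significance(n_surr=500, seed=3, alpha_forming=0.005)
print(f"channels with a significant response: "
      f"{int(sig.channel_significant.any(axis=1).sum())} / 10")
```

```
mean correlation with ground-truth kernels: 0.906
channels with a significant response: 10 / 10
```

At this noise level the estimator recovers the true kernels to r ≈ 0.9 and
the cluster statistic flags every signal-carrying channel (on pure-noise
channels it flags essentially none; see the test suite).

A thin CLI covers the shell-driven steps, e.g.
`cinetrf simulate --out sess/ --seed 3`, `cinetrf saccades --gaze
sess/gaze.tsv --out saccades.csv`, and `cinetrf trf --bha sess/bha.h5
--regressors sess/regressors.npz --out trf.h5`.

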