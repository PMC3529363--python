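# Methods

This note documents the models implemented in `burstrf`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests
do and do not establish.

## The estimation problem

A visual neuron is probed with a noise movie: dense spatiotemporal
Gaussian white noise (independent mean-zero pixels, default 20 ms frames at
33% RMS contrast; luminance is expressed throughout as mean-zero contrast,
so the pixel SD equals the RMS contrast) or sparse noise (one bright or
dark square per 29 ms frame, every pixel/sign combination shown a fixed
number of times in pseudorandom order). The analysis recovers the
spatiotemporal *subunits* (filters) whose outputs drive spiking, builds
linear–nonlinear (LN) models from them, and quantifies how much response
those models explain and how much information each subunit carries.

The thalamic complication is bursting. Relay (LGN) and reticular (PGN)
neurons fire all-or-none calcium bursts; every spike of a burst is
initiated by the stimulus that preceded the burst's first (*cardinal*)
spike. Treating later burst spikes as independent samples blurs
reverse-correlation estimates in time, so the pipeline classifies spikes
first and, by default, estimates receptive fields from cardinal plus tonic
spikes only (`spike_policy="cardinal_plus_tonic"`).

## Burst detection and representation

Detection criteria are taken literally:

* **LGN:** ≥ 2 spikes, each ISI ≤ 4 ms, following ≥ 100 ms of silence;
  the burst ends at the first ISI > 4 ms.
* **PGN:** ≥ 5 spikes within the first 70 ms (anchored at the cardinal
  spike — the anchored reading is adopted since events are *terminated*
  only by an ISI > 30 ms and typically last 70–100 ms), ISIs ≤ 30 ms,
  following ≥ 70 ms of silence.

Silence is measured from the previous spike of any kind; the first spike
of a recording counts as following infinite silence. Detection is a
single left-to-right scan, so bursts are disjoint and re-detection on the
bursts' own spikes (plus adequate silences) is idempotent.

Each burst's ISI sequence is resampled to 21 points with a monotone
piecewise-cubic (PCHIP) interpolant — shape-preserving, so a U-shaped or
monotone sequence keeps its shape without overshoot and every burst maps
into the same 21-dimensional shape space. Single-ISI bursts yield a
constant curve and are flagged.

**Clustering.** Burst curves are clustered with a Gaussian mixture whose
component count is chosen by BIC (1..`max_clusters`). Two robustness
choices matter at desk-scale sample sizes:

* *Diagonal covariances* (default). A full 21-D covariance costs ~250
  parameters per component; with a few hundred bursts the BIC penalty
  swamps the likelihood gain and even well-separated shape clusters
  collapse to one component. Diagonal covariances (43 parameters) recover
  them. `covariance_type` remains an argument.
* *Outlier gate.* A burst whose squared Mahalanobis distance to its own
  component exceeds the 99% chi-square quantile is flagged as an outlier
  (the mixture-model analogue of a spike-sorting noise cluster). Outliers
  keep their best-component assignment but are excluded from cluster
  means and from composition statements (`ClusterResult.members`).

A cluster mean counts as *U-shaped* (`is_u_shaped`) when its minimum falls
in the middle third of the burst and is below half of both boundary
intervals — reticular bursts accelerate several-fold, and the weaker
"centre below endpoints" reading also matches shallow chance wiggles.

**Autocorrelogram width** is computed from pair counts at 1 ms resolution
to ±100 ms (zero-lag bin excluded); the width is the full extent, across
zero lag, of the contiguous region around the peak exceeding 5% of the
peak bin, bridging the refractory gap at zero. Only the PGN > LGN ordering
is asserted on synthetic data; absolute widths depend on tonic rates.

## Spike-triggered analysis

The ensemble row for a spike in frame f is the flattened window of
`lag_frames` frames ending at f (frame index = ⌊t/frame_duration⌋; lag 0 is
the frame containing the spike; 6 frames of 20 ms cover 0–120 ms, the
default; the worked examples here use 5 to keep the dimension at
4×4×5 = 80). Spikes earlier than one window are excluded. The STA is the
ensemble mean. For the STC, rows are orthogonalised to the STA direction,
the residual mean is removed, and the 1/(n−1) covariance is
eigendecomposed in the orthogonal complement, so the projected-out
direction's zero eigenvalue never appears and the spectrum has D−1 ranks.

**Nested bootstrap.** Each of `n_boot` (default 1000; tests use 200)
surrogates circularly rotates all spike times by a uniform random offset of
at least one lag window, recomputes the spectrum under the same
projection, and contributes one spectrum to a per-rank null. Two details:

* Offsets are quantized to **whole stimulus frames**. A fractional offset
  splits within-frame spike clumps across frame boundaries; surrogates
  then have smoother per-frame multiplicities than the real data and their
  spectra are systematically narrower for strongly rate-modulated cells,
  producing spurious "suppressive" flags at the bottom of the spectrum.
  Whole-frame rotation preserves the multiplicity pattern exactly while
  destroying stimulus alignment.
* Per-rank bounds are the α and 1−α surrogate percentiles (α = 0.01), so
  under the null about 2αD eigenvalues per cell escape their bounds — the
  calibration the tests check on stimulus-blind cells. The *significant
  set*, however, is decided by nested testing of the spectrum's extremes
  only: if the largest (or smallest) eigenvalue escapes, its eigenvector is
  projected out of real and surrogate ensembles alike and the reduced
  spectrum re-tested until neither extreme escapes. Flagging every
  escaping rank instead would cascade (~2αD chance flags per pass) and
  essentially never report "exactly one subunit" even when exactly one
  exists. An interior eigenvalue can still become significant — by
  surfacing as an extreme once stronger subunits are removed.

The *most non-significant* subunit — used as the information bias
reference — is the eigenvector whose eigenvalue lies closest to its rank's
null median.

**Sparse noise.** STA_ON averages indicator maps of bright flashes in the
spike-triggered windows (STA_OFF likewise for dark flashes, not
sign-flipped), minus the uniform prior flash probability. Because
conditional flash probabilities sum to one, the maps carry a negative
background pedestal; each plane's median (the receptive field occupies a
minority of the grid) is subtracted before the overlap — the normalized
dot product of the two spatial maps at their common peak lag (the lag with
the most combined map energy), in percent. Whether overlap should be
computed at the peak lag or over the whole volume is not settled; peak lag
is the default and the full-volume variant is a two-line change.

## LN models

Filter output is the per-frame dot product of the trailing window with the
filter, divided by the absolute global maximum of the series (the training
series' maximum is reused at prediction time). The nonlinearity is the
mean trial-averaged spike count (PSTH, spikes per frame) in each bin of
[−1, 1]; empty bins are NaN-flagged, never interpolated, and prediction
falls back to the nearest occupied bin. By construction the
occupancy-weighted mean of the nonlinearity equals the mean training rate.

Cross-validation splits the recording into contiguous halves (train
first, test second) with a guard gap of one lag window so no test window
overlaps training frames. The bin count starts at 4 and increases in
steps of 2 until test-half explained variance drops, keeping the last
improving value; the model's free-parameter count n is the number of
occupied bins (filters are estimated on the training half only, so their
dimensions are not counted; override if your filters were fit on the same
data). 2D models default to the 1D-optimized bin count per axis.

## Evaluation

**Corrected explained variance.** With per-repeat counts d_ij (N frames,
R repeats), trial mean d̄_i, prediction m_i,

    σ² = Σ_ij (d_ij − d̄_i)² / (R·N·(R−1)),       Nσ = N(R−1),
    γ  = 1 − [Σ(d̄_i−m_i)²/σ² − (N−n)·Nσ/(Nσ−2)]
             / [Σ(d̄_i−d̄)²/σ² − (N−1)·Nσ/(Nσ−2)].

σ² is the noise variance of the *trial mean*; the (N−n) and (N−1) terms
remove the expected noise contribution from the residual and total sums,
and Nσ/(Nσ−2) compensates for σ² itself being estimated. Limits: with
noise-free repeats (σ² = 0) or R = 1 the correction is unavailable and the
naive ratio 1 − SSE/SST is returned, flagged — that reproduces γ = 1 for a
perfect noise-free model; as R grows, SSE/σ² dominates the O(N) correction
terms and γ converges to the naive ratio. Convergence is visible at
R = 64 only when per-frame counts are large enough that the trial-mean
noise floor is small against the residual — the test uses a high-rate cell
for exactly that reason. The estimator can exceed 1 by sampling noise for
near-perfect models; it is reported unclipped.

**Signal-power explained variance.** P_signal = (R·var_t(d̄) −
mean_j var_t(d_j))/(R−1), P_noise = mean_j var_t(d_j) − P_signal, and the
score is 1 − (MSE(d̄, m) − P_noise/R)/P_signal. Note an *independent*
prediction scores −var(m)/P_signal, not 0: independence costs exactly the
prediction's own variance. The two estimators agree within a few
percentage points on mid-noise synthetic cells.

**Mutual information.** I = Σ q log₂(q/p) between the spike-conditional
(q) and prior (p) filter-output histograms, scanned over bin sizes
expressed as multiples of the prior SD (default grid 0.01σ–1σ; the
pipeline uses a coarser 0.05σ–0.5σ grid for speed). Spike-conditional
samples are a subsample of the prior, so occupied conditional bins always
have prior mass; stray mass from externally supplied distributions is
merged into the best-supported prior bin. The finite-sampling bias is the
same quantity computed for the most non-significant subunit (1D), or
I(a, nonsig) − I(a) (2D), subtracted; the final value is the mean over the
stable bin-size range 0.15σ–0.4σ and the error its SD. Bias-corrected
values may be slightly negative and are reported as-is.

**Synergy** = I(STA, STC) − I(STA) − I(STC). Two calibration facts worth
knowing: (i) the exact independent-contribution limit is a *factorized*
rate r = f(g₁)·g(g₂), for which the joint spike-conditional density
separates and true synergy is 0; an additive rate r = f(g₁)+g(g₂) has
genuinely positive synergy (≈ +0.17 bits/spike for half-rectified unit
Gaussian drives, by numerical integration — the tests use that value as
the oracle). (ii) The duplication limit (synergy = −I) holds for raw
estimates; the 2-D bias term assumes a genuinely two-dimensional
distribution and over-corrects a degenerate duplicated pair.

## Subunit spatial structure

Peak dominance takes the global extrema of each sign of the spatial map at
peak lag (no subregion segmentation); ratio > 2 ⇒ single-peaked.
Single-signed maps are flagged (the "weaker peak" is noise-level). For STC
subunits the overall sign is arbitrary, so the dominant sign is reported
as indeterminate.

Reconstructions compare single-lag (peak-amplitude) spatial maps, not full
volumes. The STA model a·STA_ON + b·STA_OFF is linear in (a, b), so the
Nelder–Mead simplex solution is checked against closed-form least squares
(agreement to 1e-4 is a test invariant); separate coefficients for the
bright and dark maps are kept. The STC model is c·(STA_ON⊙STA_OFF); a
zero product map (disjoint subregions) makes c undefined and is flagged.
SNR = log₁₀(Σ real² / Σ residual²), capped at 16 for zero residuals; base
10 is a documented choice (only "logarithm" is standard) and configurable.

## The synthetic-data generator

`GroundTruthNeuron` implements rate(t) = base + g_lin·f(z_lin) +
g_quad·z_quad² + g_off·relu(−z_off), drives in units of their theoretical
SD, f half-wave rectification (or identity). The `off_filter` term models
push-push cells with an excitatory dark-driven subregion — needed for
sparse-noise ON/OFF tests, where a single signed filter would produce
push-pull maps contaminated by suppression. Tonic spikes are an
inhomogeneous Poisson process at 1 ms resolution (finer than the tightest
4 ms criterion) **with a 4 ms absolute refractory period** (dead-time
corrected hazard, so nominal rates are preserved): thalamic neurons reach
sub-4-ms ISIs only inside calcium bursts — the very fact the relay burst
criterion exploits — and without the refractory term chance tonic doublet
chains mimic burst ISI patterns.

Bursts are inserted when the drive crosses `burst_threshold_sd` (default
2 SD) at a frame onset *and* the preceding silence exceeds the profile's
refractory requirement (100 ms LGN, 70 ms PGN). Burst spikes follow a
fixed ISI template with clipped Gaussian jitter — decelerating
[2, 2.5, 3, 3.5] ms (5 spikes, jitter 0.1 ms) for LGN; U-shaped
[15, 10, 6, 4, 6, 10, 15, 20] ms (9 spikes, 86 ms, jitter 1 ms) for PGN,
which places 8 spikes inside the first 70 ms. Tonic spiking is suppressed
during the burst and for one burst-terminating ISI afterwards (all-or-none
phenomenology, and it prevents a trailing tonic spike from artificially
extending the detected event). Bursts truncated by the stimulus end are
logged.

Stock cells (`default_neuron`) use moderate tonic rates (~10 spikes/s
means; base 3 spikes/s, linear gain ~10 spikes/s per drive-SD), chosen so
that, as in recordings, the silences bursts require actually occur and
chance tonic runs only rarely satisfy burst criteria. Seeds jitter subunit
centres and gains so cell banks have genuinely different receptive fields.

**What the generator does not emulate:** spike-history dependence beyond
the refractory/dead-time terms, adaptation to luminance or contrast,
correlated (naturalistic) stimuli, membrane-potential dynamics of burst
initiation (threshold-on-drive is a caricature), eye movements, recording
noise, or spike-sorting errors. Passing tests therefore establish that the
estimators recover what they claim under an LN-plus-bursts world at
realistic counts — not that real thalamic data satisfy those assumptions.

## Problem sizes

Tests and the acceptance script run on 4×4 grids with 5 stimulus lags
(D = 80), 4096–8192 frames of 20 ms, 1–8 repeats, 200 bootstrap
surrogates, and cell banks of 3–10 neurons — sizes at which the full suite
and the acceptance run each complete in a few minutes on one CPU while
keeping ≥ 50 spikes per stimulus dimension where recovery accuracy is
asserted. All sizes are ordinary function arguments; nothing in the code
assumes them.

## Known limitations

* The bootstrap's per-rank bounds are pointwise, not simultaneous; the
  extreme-rank nesting is what keeps the final significant set
  conservative.
* The information estimator's stable-range averaging assumes the bias is
  flat over 0.15σ–0.4σ; heavily non-Gaussian filter outputs may need a
  different range.
* Chance tonic events that satisfy the reticular burst criteria *and* have
  deeply U-shaped ISI curves are statistically unavoidable at a rate of
  roughly one per few hundred events; the outlier gate removes most, not
  all, so cluster-purity statements are probabilistic.
* Sparse-noise maps assume one flash per frame and uniform visiting;
  arbitrary sparse designs would need their own prior correction.
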