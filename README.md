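# burstrf

Receptive-field estimation for **bursting thalamic neurons** — relay cells
of the lateral geniculate nucleus (LGN) and the inhibitory neurons of the
perigeniculate sector (PGN) of the thalamic reticular nucleus.

Standard reverse-correlation methods assume every spike is independently
driven by the stimulus. Thalamic neurons violate that assumption: they fire
all-or-none calcium bursts in which one stimulus event triggers a whole
train of spikes. `burstrf` provides the analysis chain needed to map visual
receptive fields in this regime, together with a synthetic-data generator
(stimuli + ground-truth model neurons with burst dynamics) so every stage
can be validated against known answers. It is aimed at systems
neuroscientists analysing spike trains recorded during noise stimulation,
and at anyone who needs a tested reference implementation of
spike-triggered covariance with bootstrap significance, burst-aware spike
selection, or bias-corrected model evaluation.

## What it computes

**Burst detection and classification** (`burstrf.bursts`). Relay-cell
bursts: ≥2 spikes, inter-spike intervals (ISIs) ≤ 4 ms, after ≥ 100 ms of
silence. Reticular bursts: ≥5 spikes within 70 ms, ISIs ≤ 30 ms, after
≥ 70 ms of silence, terminated by an ISI > 30 ms. Each burst's ISI
sequence is resampled to a 21-point shape-preserving curve; a
BIC-selected Gaussian mixture clusters these curves, separating the
U-shaped (accelerating–decelerating) reticular pattern from the
monotonically decelerating relay pattern.

**Subunit recovery** (`burstrf.spiketrig`). With stimulus window
**s**(t) and spike train y(t), the spike-triggered average
STA = ⟨**s** | spike⟩ gives the first-order subunit; eigenvectors of the
spike-triggered covariance (STA projected out) give second-order subunits.
Because all spikes of a burst are initiated by the stimulus preceding the
first (*cardinal*) spike, later burst spikes are excluded
(`spike_policy="cardinal_plus_tonic"`). Eigenvalue significance is
assessed by a nested bootstrap: the spike train is circularly rotated in
time (whole stimulus frames, preserving its internal statistics), the
spectrum recomputed per surrogate, and per-rank confidence bounds built;
significant extremes are projected out and the remainder re-tested.

**LN models** (`burstrf.lnmodel`). `LNModel1D` / `LNModel2D` are
scikit-learn-style estimators: the filter output
g(t) = **k**·**s**(t), normalized so ±1 marks maximal same/opposite-sign
similarity, is mapped to firing rate through a binned nonlinearity
r = N(g) (or a joint N(g₁, g₂) for two subunits), with the bin count
chosen by cross-validation.

**Evaluation** (`burstrf.evaluation`). Explained variance corrected for
finite repeats and free parameters,

    γ = 1 − [Σᵢ(d̄ᵢ−mᵢ)²/σ² − (N−n)·Nσ/(Nσ−2)] / [Σᵢ(d̄ᵢ−d̄)²/σ² − (N−1)·Nσ/(Nσ−2)],

with σ² the noise variance of the trial-mean PSTH and Nσ = N(R−1); a
signal-power estimator as an independent check; and mutual information
(bits/spike) of each subunit as the Kullback–Leibler divergence between
spike-conditional and prior filter-output distributions, with a
finite-sampling bias (measured on the most non-significant subunit)
subtracted. Synergy = I(joint) − I(STA) − I(STC).

**Spatial structure** (`burstrf.rfmetrics`). Peak-dominance ratio
(stronger ÷ weaker opposite-sign peak; > 2 = single-peaked), and tests of
whether dense-noise subunits are explained by sparse-noise ON/OFF maps:
model STA = a·STA_ON + b·STA_OFF (weighted sum), model
STC = c·STA_ON⊙STA_OFF (pixel-wise product), coefficients fitted by
Nelder–Mead simplex on the squared error, goodness quantified as
log₁₀(subunit power / residual power).

## Worked example

```python
import numpy as np
from burstrf import *
from burstrf.synthetic import default_neuron
from burstrf.pipeline import train_test_split_frames, slice_stimulus

stim = make_gaussian_noise((4, 4), n_frames=8192, frame_duration=0.020,
                           rms_contrast=0.33, seed=0)
neuron = default_neuron("pgn_two_subunit", seed=0)   # known subunits + bursts
rec = simulate_response(neuron, stim, n_repeats=4, seed=1)

bursts = detect_bursts_pgn(rec.repeats[0])
res = bootstrap_significance(stim, rec, lag_frames=5, n_boot=200, seed=2)
sta = compute_sta(build_ensemble(stim, rec, 5, "all"))

psth = compute_psth(rec, stim.n_frames, stim.frame_duration)
tr, te = train_test_split_frames(stim.n_frames, 5)
m1 = LNModel1D(filt=sta, n_bins=10).fit(slice_stimulus(stim, tr), psth.slice(tr))
m2 = LNModel2D(filt_a=sta, filt_b=res.significant_filters()[0],
               n_bins=10).fit(slice_stimulus(stim, tr), psth.slice(tr))
g1 = explained_variance_corrected(psth.slice(te),
                                  m1.predict(slice_stimulus(stim, te)),
                                  m1.n_free_params_)
g2 = explained_variance_corrected(psth.slice(te),
                                  m2.predict(slice_stimulus(stim, te)),
                                  m2.n_free_params_)
```

Output:

```
9911 spikes over 4 repeats
65 reticular-criteria bursts; first burst: 9 spikes over 86 ms
1 significant STC subunit(s); top eigenvalue 0.186 vs null bound 0.152
STA vs ground-truth filter cosine: 0.911
corrected explained variance: 1D 43.2%, 2D 58.8%
```

Reading this: the simulated reticular cell fired 65 detectable bursts in
one 164 s repeat; the nested bootstrap found exactly the one quadratic
subunit that was built into the cell (its eigenvalue, 0.186, escapes the
99% null bound, 0.152); the recovered STA points at the true linear
filter; and adding the STC subunit to the LN model raises the
cross-validated, bias-corrected explained variance from 43% to 59% — the
second-order subunit carries response structure the STA alone misses.

A command-line interface wraps each stage
(`burstrf simulate | detect-bursts | cluster-bursts | sta | stc |
sparse-map | fit-ln | rf-metrics | run`); intermediate results live in a
single HDF5 container per run (`/stimulus/frames`, `/spikes/repeat_<i>`,
`/labels/repeat_<i>`, `/filters/<kind>_<k>`), with a plain NPZ fallback.
`burstrf run --config cfg.yaml` executes the full pipeline
(simulate → detect → map → fit → evaluate → report) deterministically
from a seeded YAML config.

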