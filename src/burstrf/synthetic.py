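"""Synthetic stimuli and ground-truth LN neurons with burst dynamics.

This module generates everything the analysis stages consume, so the whole
pipeline can be exercised and validated without recorded data:

* dense spatiotemporal Gaussian white noise (default 20 ms frames, 33% RMS
  contrast) and sparse noise (one bright or dark square flashed per 29 ms
  frame, each pixel/sign combination visited a fixed number of times in
  pseudorandom order);
* linear-nonlinear (LN) model neurons with known first-order (STA-like) and
  optional second-order (STC-like, squared-drive) subunits;
* thalamic burst dynamics: relay-cell-like (LGN) bursts with short
  *decelerating* inter-spike intervals, and reticular-cell-like (PGN)
  bursts whose ISIs first shorten then lengthen (U-shaped), inserted
  whenever the stimulus drive crosses a threshold after a sufficient
  period of silence.

Spiking is discretised at 1 ms (finer than the tightest 4 ms ISI criterion);
burst spike times keep their continuous template values.  Everything is
reproducible given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from burstrf.datatypes import SpikeRecord, StimulusMovie, SubunitFilter

logger = logging.getLogger(__name__)

__all__ = [
    "GroundTruthNeuron",
    "make_gaussian_noise",
    "make_sparse_noise",
    "simulate_response",
    "make_blob_filter",
    "default_neuron",
    "LGN_ISI_TEMPLATE_MS",
    "PGN_ISI_TEMPLATE_MS",
]

#: Decelerating ISI template (ms) for relay-cell-like bursts: every interval
#: is <= 4 ms and grows with each successive spike (5 spikes, ~11 ms burst).
LGN_ISI_TEMPLATE_MS = np.array([2.0, 2.5, 3.0, 3.5])

#: U-shaped ISI template (ms) for reticular-cell-like bursts: intervals first
#: shorten, then lengthen (9 spikes over 86 ms; 8 spikes fall inside the
#: first 70 ms and every interval is <= 30 ms).
PGN_ISI_TEMPLATE_MS = np.array([15.0, 10.0, 6.0, 4.0, 6.0, 10.0, 15.0, 20.0])

_SPIKE_DT = 1e-3  # tonic-spike discretisation, seconds

#: Absolute refractory period of *tonic* spiking, ms.  Thalamic neurons fire
#: sub-4-ms inter-spike intervals only within calcium bursts — that is why
#: the relay-cell burst criterion uses the 4 ms cutoff — so tonic sampling
#: enforces this dead time (with the hazard corrected so the nominal rate is
#: preserved).
TONIC_REFRACTORY_MS = 4.0


def _dead_time_filter(idx: np.ndarray, min_gap: int) -> np.ndarray:
    """Greedy renewal filter: keep spikes at least ``min_gap`` bins apart."""
    keep = []
    last = -min_gap
    for i in idx:
        if i - last >= min_gap:
            keep.append(i)
            last = i
    return np.asarray(keep, dtype=np.int64)


def make_gaussian_noise(
    grid_shape: tuple[int, int],
    n_frames: int,
    frame_duration: float = 0.020,
    rms_contrast: float = 0.33,
    seed: int = 0,
) -> StimulusMovie:
    """Spatiotemporal Gaussian white noise.

    Each pixel of each frame is an independent draw from a zero-mean
    Gaussian whose standard deviation equals ``rms_contrast``.
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1 or n_frames < 1:
        raise ValueError("grid dimensions and frame count must be positive")
    if not 0 < rms_contrast <= 1:
        raise ValueError("rms_contrast must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    frames = rng.normal(0.0, rms_contrast, size=(n_frames, rows, cols))
    return StimulusMovie(
        frames=frames,
        frame_duration=frame_duration,
        kind="gaussian",
        rms_contrast=rms_contrast,
        seed=seed,
    )


def make_sparse_noise(
    grid_shape: tuple[int, int],
    n_presentations: int = 16,
    frame_duration: float = 0.029,
    contrast: float = 0.5,
    seed: int = 0,
) -> StimulusMovie:
    """Sparse noise: one bright or dark square flashed per frame.

    Every (pixel, sign) combination appears exactly ``n_presentations``
    times, in a seeded pseudorandom order, giving
    ``rows * cols * 2 * n_presentations`` frames in total.
    """
    rows, cols = grid_shape
    if rows < 1 or cols < 1 or n_presentations < 1:
        raise ValueError("grid dimensions and presentation count must be positive")
    if not 0 < contrast <= 1:
        raise ValueError("contrast must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    n_pix = rows * cols
    pix = np.tile(np.arange(n_pix), 2 * n_presentations)
    sign = np.tile(np.repeat([1.0, -1.0], n_pix), n_presentations)
    order = rng.permutation(pix.size)
    pix, sign = pix[order], sign[order]
    frames = np.zeros((pix.size, rows, cols))
    frames[np.arange(pix.size), pix // cols, pix % cols] = sign * contrast
    return StimulusMovie(
        frames=frames,
        frame_duration=frame_duration,
        kind="sparse",
        rms_contrast=contrast,
        seed=seed,
    )


def _biphasic_temporal(n_lags: int, peak_lag: int = 2) -> np.ndarray:
    """Biphasic temporal kernel over lags (lag 0 = frame of the spike)."""
    lags = np.arange(n_lags, dtype=float)
    main = np.exp(-0.5 * ((lags - peak_lag) / 0.9) ** 2)
    rebound = -0.45 * np.exp(-0.5 * ((lags - peak_lag - 2.2) / 1.2) ** 2)
    return main + rebound


def make_blob_filter(
    grid_shape: tuple[int, int],
    n_lags: int = 5,
    center: tuple[float, float] | None = None,
    sigma: float = 0.9,
    sign: float = 1.0,
    peak_lag: int = 2,
) -> SubunitFilter:
    """Unit-norm spatiotemporal filter: Gaussian blob x biphasic time course."""
    rows, cols = grid_shape
    if center is None:
        center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    rr, cc = np.mgrid[0:rows, 0:cols]
    space = np.exp(-0.5 * (((rr - center[0]) / sigma) ** 2
                           + ((cc - center[1]) / sigma) ** 2))
    w = sign * _biphasic_temporal(n_lags, peak_lag)[:, None, None] * space[None]
    w /= np.linalg.norm(w)
    return SubunitFilter(weights=w, kind="model")


@dataclass
class GroundTruthNeuron:
    """An LN neuron with known subunits and optional burst dynamics.

    The instantaneous rate at stimulus frame *t* is::

        rate(t) = base_rate + lin_gain * f(z_lin(t)) + quad_gain * z_quad(t)**2

    where ``z_lin``/``z_quad`` are the linear/quadratic filter drives in
    units of their theoretical standard deviation and ``f`` is the named
    ``output_nonlinearity`` (``halfwave`` rectification by default, or
    ``linear``).  An optional ``off_filter`` adds an *excitatory OFF*
    subregion, ``off_gain * relu(-z_off)``, so push-push cells with
    separate bright- and dark-driven subregions can be modelled.  Tonic spikes are drawn as an inhomogeneous Poisson process
    at 1 ms resolution.  When ``burst_profile`` is not ``"none"``, a burst is
    inserted whenever the drive exceeds ``burst_threshold_sd`` (in drive-SD
    units) at a frame onset *and* the preceding silence exceeds
    ``refractory_silence_ms``; burst spikes follow ``isi_template_ms`` with
    Gaussian jitter, and tonic spiking is suppressed during the burst and
    for one burst-terminating interval afterwards (all-or-none
    calcium-burst phenomenology).
    """

    linear_filter: SubunitFilter
    quad_filter: SubunitFilter | None = None
    off_filter: SubunitFilter | None = None
    output_nonlinearity: str = "halfwave"
    base_rate: float = 4.0
    lin_gain: float = 30.0
    quad_gain: float = 0.0
    off_gain: float = 0.0
    burst_profile: str = "none"
    isi_template_ms: np.ndarray | None = None
    isi_jitter_ms: float | None = None
    refractory_silence_ms: float | None = None
    burst_threshold_sd: float = 2.0

    def __post_init__(self) -> None:
        for f in (self.linear_filter, self.quad_filter, self.off_filter):
            if f is not None:
                nrm = np.linalg.norm(f.weights)
                if nrm > 0:
                    f.weights = f.weights / nrm
        if self.output_nonlinearity not in ("halfwave", "linear"):
            raise ValueError("output_nonlinearity must be 'halfwave' or 'linear'")
        if self.burst_profile not in ("none", "lgn_decelerating", "pgn_u_shaped"):
            raise ValueError(f"unknown burst_profile {self.burst_profile!r}")
        if self.burst_profile == "lgn_decelerating":
            self.isi_template_ms = (LGN_ISI_TEMPLATE_MS.copy()
                                    if self.isi_template_ms is None
                                    else np.asarray(self.isi_template_ms, float))
            if self.isi_jitter_ms is None:
                self.isi_jitter_ms = 0.1
            if self.refractory_silence_ms is None:
                self.refractory_silence_ms = 100.0
            if np.any(np.diff(self.isi_template_ms) < 0):
                raise ValueError("LGN ISI template must be non-decreasing")
        elif self.burst_profile == "pgn_u_shaped":
            self.isi_template_ms = (PGN_ISI_TEMPLATE_MS.copy()
                                    if self.isi_template_ms is None
                                    else np.asarray(self.isi_template_ms, float))
            if self.isi_jitter_ms is None:
                self.isi_jitter_ms = 1.0
            if self.refractory_silence_ms is None:
                self.refractory_silence_ms = 70.0
            d = np.sign(np.diff(self.isi_template_ms))
            flips = np.count_nonzero(np.diff(d[d != 0]) != 0)
            if flips != 1 or d[d != 0][0] >= 0:
                raise ValueError("PGN ISI template must decrease then increase")

    @property
    def n_lags(self) -> int:
        return self.linear_filter.n_lags

    def rate_trace(self, stimulus: StimulusMovie) -> np.ndarray:
        """Expected firing rate (spikes/s) at each stimulus frame."""
        z_lin = _drive(stimulus, self.linear_filter)
        rate = np.full(stimulus.n_frames, float(self.base_rate))
        if self.lin_gain:
            f = np.maximum(z_lin, 0.0) if self.output_nonlinearity == "halfwave" else z_lin
            rate = rate + self.lin_gain * f
        if self.quad_filter is not None and self.quad_gain:
            z_q = _drive(stimulus, self.quad_filter)
            rate = rate + self.quad_gain * z_q ** 2
        if self.off_filter is not None and self.off_gain:
            # excitatory OFF subregion: half-rectified response to the
            # *negated* drive, i.e. dark stimuli over this subunit excite
            z_off = _drive(stimulus, self.off_filter)
            rate = rate + self.off_gain * np.maximum(-z_off, 0.0)
        return np.maximum(rate, 0.0)

    def burst_drive(self, stimulus: StimulusMovie) -> np.ndarray:
        """Normalized drive that gates burst insertion."""
        if self.lin_gain or self.quad_filter is None:
            return _drive(stimulus, self.linear_filter)
        return _drive(stimulus, self.quad_filter) ** 2


def _drive(stimulus: StimulusMovie, filt: SubunitFilter) -> np.ndarray:
    """Per-frame filter drive in units of its theoretical SD.

    For a unit-norm filter and white Gaussian pixels of SD ``rms_contrast``
    the raw drive has SD ``rms_contrast``.  Frames earlier than the filter
    length get zero drive.
    """
    n_lags = filt.n_lags
    flat = stimulus.frames.reshape(stimulus.n_frames, -1)
    w = filt.weights.reshape(n_lags, -1)
    out = np.zeros(stimulus.n_frames)
    for lag in range(n_lags):
        # weight plane `lag` multiplies the frame `n_lags-1-lag` steps back
        contrib = flat @ w[lag]
        shift = n_lags - 1 - lag
        if shift:
            out[shift:] += contrib[:-shift]
        else:
            out += contrib
    out[: n_lags - 1] = 0.0
    return out / stimulus.rms_contrast


def simulate_response(
    neuron: GroundTruthNeuron,
    stimulus: StimulusMovie,
    n_repeats: int = 1,
    seed: int = 0,
) -> SpikeRecord:
    """Simulate spike trains of ``neuron`` responding to ``stimulus``.

    Returns a :class:`SpikeRecord` whose ``meta`` records, per repeat, the
    inserted burst cardinal times (``burst_times``) and triggering frame
    indices (``burst_frames``), plus the expected per-frame rate trace
    (``rate_per_frame``) — the ground truth downstream recovery is tested
    against.  ``labels`` codes: 0 tonic, 1 cardinal, 2 later burst spike.
    """
    if neuron.n_lags > stimulus.n_frames:
        raise ValueError("neuron filter has more lags than the stimulus has frames")
    rng = np.random.default_rng(seed)
    rate = neuron.rate_trace(stimulus)
    frame_dur = stimulus.frame_duration
    duration = stimulus.duration
    n_ms = int(round(duration / _SPIKE_DT))
    # per-1ms spike probability from the frame-constant rate
    ms_frame = np.minimum((np.arange(n_ms) * _SPIKE_DT / frame_dur).astype(int),
                          stimulus.n_frames - 1)
    p_ms = rate[ms_frame] * _SPIKE_DT
    # dead-time-corrected hazard so the nominal rate survives the tonic
    # refractory period: h = lambda / (1 - lambda * tau)
    tau_ms = int(round(TONIC_REFRACTORY_MS))
    p_draw = np.clip(p_ms / np.maximum(1.0 - p_ms * tau_ms, 0.2), 0, 0.9)

    bursting = neuron.burst_profile != "none"
    if bursting:
        z = neuron.burst_drive(stimulus)
        eligible = np.flatnonzero(z >= neuron.burst_threshold_sd)
        silence_s = neuron.refractory_silence_ms * 1e-3
        template_s = np.asarray(neuron.isi_template_ms) * 1e-3
        jitter_s = neuron.isi_jitter_ms * 1e-3
        term_isi_s = (4.0 if neuron.burst_profile == "lgn_decelerating" else 30.0) * 1e-3

    repeats, labels, all_burst_times, all_burst_frames = [], [], [], []
    for _ in range(n_repeats):
        cand = np.flatnonzero(rng.random(n_ms) < p_draw)
        tonic = _dead_time_filter(cand, tau_ms) * _SPIKE_DT
        burst_spikes: list[np.ndarray] = []
        burst_frames: list[int] = []
        suppress: list[tuple[float, float]] = []
        if bursting:
            for t in eligible:
                t0 = t * frame_dur + 1e-3  # cardinal 1 ms into the frame
                # last spike of any kind before the candidate cardinal
                idx = int(np.searchsorted(tonic, t0)) - 1
                while idx >= 0 and any(a < tonic[idx] < b for a, b in suppress):
                    idx -= 1
                last = tonic[idx] if idx >= 0 else -np.inf
                if burst_spikes:
                    last = max(last, burst_spikes[-1][-1])
                if t0 - last < silence_s:
                    continue
                isis = template_s + np.clip(
                    rng.normal(0.0, jitter_s, template_s.size),
                    -3 * jitter_s, 3 * jitter_s)
                spikes = t0 + np.concatenate([[0.0], np.cumsum(isis)])
                if spikes[-1] >= duration:
                    spikes = spikes[spikes < duration]
                    logger.warning("burst at %.3f s truncated by stimulus end", t0)
                    if spikes.size == 0:
                        continue
                burst_spikes.append(spikes)
                burst_frames.append(int(t))
                suppress.append((t0 - 1e-9, spikes[-1] + term_isi_s + 1e-3))
        keep = np.ones(tonic.size, dtype=bool)
        for a, b in suppress:
            keep &= ~((tonic > a) & (tonic < b))
        tonic = tonic[keep]
        parts = [tonic] + burst_spikes
        lab_parts = [np.zeros(tonic.size, dtype=np.int64)]
        for s in burst_spikes:
            lab = np.full(s.size, 2, dtype=np.int64)
            lab[0] = 1
            lab_parts.append(lab)
        times = np.concatenate(parts)
        labs = np.concatenate(lab_parts)
        order = np.argsort(times, kind="stable")
        repeats.append(times[order])
        labels.append(labs[order])
        all_burst_times.append(np.array([s[0] for s in burst_spikes]))
        all_burst_frames.append(np.asarray(burst_frames, dtype=np.int64))

    return SpikeRecord(
        repeats=repeats,
        labels=labels,
        meta={
            "burst_times": all_burst_times,
            "burst_frames": all_burst_frames,
            "rate_per_frame": rate,
            "seed": seed,
        },
    )


def default_neuron(
    kind: str,
    grid_shape: tuple[int, int] = (4, 4),
    n_lags: int = 5,
    seed: int = 0,
    **overrides,
) -> GroundTruthNeuron:
    """Stock ground-truth neurons used throughout tests and demos.

    kinds
    -----
    ``lgn_linear``
        Half-rectified single-subunit relay-like cell with decelerating
        bursts.
    ``pgn_two_subunit``
        Reticular-like cell: half-rectified linear subunit plus a squared
        (energy) subunit, U-shaped bursts.
    ``energy``
        Pure quadratic (energy-model) cell, no bursts — the STC test case.
    ``blind``
        Stimulus-independent Poisson cell (all gains zero).

    ``seed`` jitters the subunit centres and gains so that banks of cells
    built with different seeds have genuinely different receptive fields.
    """
    rows, cols = grid_shape
    rng = np.random.default_rng(seed)
    jit = rng.uniform(-0.5, 0.5, size=4)
    gain_scale = rng.uniform(0.8, 1.25, size=2)
    lin = make_blob_filter(grid_shape, n_lags,
                           center=((rows - 1) / 2 - 0.5 + jit[0],
                                   (cols - 1) / 2 - 0.5 + jit[1]))
    # quadratic subunit: displaced blob, orthogonalised to the linear one
    quad = make_blob_filter(grid_shape, n_lags,
                            center=((rows - 1) / 2 + 0.7 + jit[2],
                                    (cols - 1) / 2 + 0.7 + jit[3]),
                            sigma=0.7, peak_lag=2)
    q = quad.flat - (quad.flat @ lin.flat) * lin.flat
    quad.weights = (q / np.linalg.norm(q)).reshape(quad.weights.shape)

    # tonic rates are kept moderate (~10 spikes/s) so that, as in recordings,
    # the silences required before calcium bursts actually occur and tonic
    # spikes only rarely mimic a burst by chance
    if kind == "lgn_linear":
        params = dict(linear_filter=lin, base_rate=3.0,
                      lin_gain=10.0 * gain_scale[0],
                      burst_profile="lgn_decelerating")
    elif kind == "pgn_two_subunit":
        params = dict(linear_filter=lin, quad_filter=quad, base_rate=3.0,
                      lin_gain=10.0 * gain_scale[0],
                      quad_gain=4.0 * gain_scale[1],
                      burst_profile="pgn_u_shaped")
    elif kind == "energy":
        params = dict(linear_filter=lin, quad_filter=quad, base_rate=2.0,
                      lin_gain=0.0, quad_gain=12.0 * gain_scale[1])
    elif kind == "blind":
        params = dict(linear_filter=lin, base_rate=20.0, lin_gain=0.0)
    else:
        raise ValueError(f"unknown neuron kind {kind!r}")
    params.update(overrides)
    return GroundTruthNeuron(**params)
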