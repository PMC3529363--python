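"""Spike-triggered ensemble analysis: STA, STC and significance testing.

The spike-triggered stimulus ensemble collects, for every eligible spike,
the ``lag_frames`` stimulus frames up to and including the frame containing
the spike (lag 0 = the coincident frame; 6 frames of 20 ms cover 0-120 ms).
Its mean is the spike-triggered average (STA); the eigenvectors of its
covariance, after the STA direction is projected out, are the
spike-triggered covariance (STC) subunits.

For bursting neurons the ensemble should contain one spike per burst (the
*cardinal* spike) plus the tonic spikes — later burst spikes are driven by
the same stimulus as the cardinal and would blur the estimate.  The
``spike_policy`` argument selects the convention.

Significance of STC eigenvalues is assessed with a nested bootstrap: the
spike train is circularly rotated in time by a uniform random offset
(preserving all spike-train statistics while destroying the stimulus
alignment), the spectrum recomputed, and a per-rank two-sided confidence
interval built from the surrogate spectra.  Eigenvalues falling outside
their rank's interval are significant; each newly significant eigenvector
is projected out and the remainder re-tested until no more are added.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from burstrf.bursts import LABEL_CARDINAL, LABEL_TONIC, SpikeClassification
from burstrf.datatypes import OnOffMaps, SpikeRecord, StimulusMovie, SubunitFilter

logger = logging.getLogger(__name__)

__all__ = [
    "SpikeTriggeredEnsemble", "STCResult",
    "build_ensemble", "compute_sta", "compute_stc",
    "bootstrap_significance", "sparse_sta",
]

_POLICIES = ("all", "cardinal_plus_tonic", "tonic_only", "cardinal_only")


@dataclass
class SpikeTriggeredEnsemble:
    """Stimulus windows preceding each included spike.

    ``matrix`` is (n_spikes, D) with D = lag_frames * rows * cols; row *i*
    is frames ``[f-lag_frames+1 .. f]`` flattened, where *f* is the frame
    containing spike *i*.  Spikes within ``lag_frames`` of stimulus onset
    are excluded.
    """

    matrix: np.ndarray
    lag_frames: int
    frame_duration: float
    grid_shape: tuple[int, int]
    spike_policy: str
    spike_frames: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    @property
    def n_spikes(self) -> int:
        return self.matrix.shape[0]

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def reshape_filter(self, flat: np.ndarray, **kw) -> SubunitFilter:
        rows, cols = self.grid_shape
        return SubunitFilter(
            weights=flat.reshape(self.lag_frames, rows, cols), **kw)


@dataclass
class STCResult:
    """Eigen-spectrum of the spike-triggered covariance.

    ``eigenvalues`` are sorted descending (length D-1 once the STA direction
    has been projected out and its zero eigenvalue dropped).  When the
    bootstrap has been run, ``ci_lower``/``ci_upper`` hold the per-rank null
    bounds, ``null_median`` the per-rank null medians, and
    ``significant_indices`` the ranks whose eigenvalue escapes its interval.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (n_ranks, D), unit norm
    lag_frames: int
    grid_shape: tuple[int, int]
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    null_median: np.ndarray | None = None
    significant_indices: list[int] = field(default_factory=list)

    def filter_at(self, rank: int) -> SubunitFilter:
        rows, cols = self.grid_shape
        return SubunitFilter(
            weights=self.eigenvectors[rank].reshape(self.lag_frames, rows, cols),
            kind=f"STC_{rank + 1}",
            eigenvalue=float(self.eigenvalues[rank]),
            significant=rank in self.significant_indices,
            rank=rank + 1,
        )

    def significant_filters(self) -> list[SubunitFilter]:
        return [self.filter_at(r) for r in sorted(self.significant_indices)]

    def most_nonsignificant_filter(self) -> SubunitFilter:
        """Eigenvector whose eigenvalue sits closest to the null median.

        By construction it carries no stimulus information beyond
        finite-sampling bias, which is exactly what the information
        estimators subtract.
        """
        if self.null_median is None:
            raise ValueError("bootstrap has not been run")
        dist = np.abs(self.eigenvalues - self.null_median)
        if self.significant_indices:
            dist[list(self.significant_indices)] = np.inf
        return self.filter_at(int(np.argmin(dist)))


def _eligible_times(record: SpikeRecord, policy: str,
                    classifications=None) -> list[np.ndarray]:
    """Spike times per repeat satisfying the spike policy."""
    if policy not in _POLICIES:
        raise ValueError(f"unknown spike policy {policy!r}")
    if policy == "all":
        return list(record.repeats)
    if classifications is not None:
        label_arrays = [
            c.labels if isinstance(c, SpikeClassification) else np.asarray(c)
            for c in classifications
        ]
    elif record.labels is not None:
        label_arrays = record.labels
    else:
        raise ValueError(
            f"spike policy {policy!r} requires classified spikes; pass "
            "`classifications` or use a record with labels")
    out = []
    for times, labels in zip(record.repeats, label_arrays):
        if policy == "cardinal_plus_tonic":
            mask = (labels == LABEL_TONIC) | (labels == LABEL_CARDINAL)
        elif policy == "tonic_only":
            mask = labels == LABEL_TONIC
        else:  # cardinal_only
            mask = labels == LABEL_CARDINAL
        out.append(times[mask])
    return out


def _window_matrix(stimulus: StimulusMovie, lag_frames: int) -> np.ndarray:
    """(n_frames - lag + 1, D) view: row k = frames [k .. k+lag-1] flattened."""
    flat = stimulus.frames.reshape(stimulus.n_frames, -1)
    sw = sliding_window_view(flat, (lag_frames, flat.shape[1]))[:, 0]
    return sw.reshape(sw.shape[0], -1)


def build_ensemble(
    stimulus: StimulusMovie,
    spike_record: SpikeRecord,
    lag_frames: int = 6,
    spike_policy: str = "cardinal_plus_tonic",
    classifications=None,
) -> SpikeTriggeredEnsemble:
    """Collect the stimulus window preceding every eligible spike.

    Frame assignment is ``floor(spike_time / frame_duration)`` and the
    window ends with the frame containing the spike.  All repeats of the
    record are pooled (the stimulus is frozen across repeats).
    """
    if lag_frames < 1:
        raise ValueError("lag_frames must be >= 1")
    W = _window_matrix(stimulus, lag_frames)
    frames_per_repeat = []
    for times in _eligible_times(spike_record, spike_policy, classifications):
        f = np.floor(times / stimulus.frame_duration).astype(np.int64)
        f = f[(f >= lag_frames - 1) & (f < stimulus.n_frames)]
        frames_per_repeat.append(f)
    frames = (np.concatenate(frames_per_repeat) if frames_per_repeat
              else np.empty(0, dtype=np.int64))
    if frames.size == 0:
        raise ValueError("no eligible spikes within the stimulus window")
    matrix = W[frames - (lag_frames - 1)].copy()
    return SpikeTriggeredEnsemble(
        matrix=matrix, lag_frames=lag_frames,
        frame_duration=stimulus.frame_duration,
        grid_shape=stimulus.grid_shape,
        spike_policy=spike_policy, spike_frames=frames)


def compute_sta(ensemble: SpikeTriggeredEnsemble) -> SubunitFilter:
    """Spike-triggered average: the column-wise ensemble mean."""
    if ensemble.n_spikes == 0:
        raise ValueError("empty ensemble")
    return ensemble.reshape_filter(ensemble.matrix.mean(axis=0), kind="STA")


def _complement_basis(directions: np.ndarray, dim: int) -> np.ndarray:
    """Orthonormal basis (dim, dim-k) of the complement of k directions."""
    if directions.size == 0:
        return np.eye(dim)
    q, _ = np.linalg.qr(directions.T)
    proj = np.eye(dim) - q @ q.T
    u, s, _ = np.linalg.svd(proj)
    return u[:, : dim - directions.shape[0]]


def _stc_spectrum(matrix: np.ndarray, basis: np.ndarray):
    """Eigen-spectrum of the ensemble covariance within ``basis``'s span.

    Rows are projected into the orthogonal-complement coordinates, the mean
    removed, and the 1/(n-1)-normalised covariance eigendecomposed.
    Eigenvectors are mapped back to stimulus space.
    """
    y = matrix @ basis
    y = y - y.mean(axis=0)
    n = y.shape[0]
    cov = (y.T @ y) / max(n - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    return vals[order], (basis @ vecs[:, order]).T


def compute_stc(
    ensemble: SpikeTriggeredEnsemble,
    sta: SubunitFilter | None = None,
) -> STCResult:
    """Spike-triggered covariance spectrum with the STA projected out.

    The ensemble rows are orthogonalised to the STA direction, the ensemble
    mean removed, and the covariance matrix eigendecomposed; the zero
    eigenvalue created by the projection is dropped, leaving a descending
    spectrum of length D-1.
    """
    if sta is None:
        sta = compute_sta(ensemble)
    d = ensemble.dim
    if ensemble.n_spikes < d:
        logger.warning("ensemble has fewer spikes (%d) than dimensions (%d)",
                       ensemble.n_spikes, d)
    sta_flat = sta.flat
    nrm = np.linalg.norm(sta_flat)
    if nrm == 0:
        logger.warning("zero-norm STA: skipping projection")
        basis = np.eye(d)
    else:
        basis = _complement_basis((sta_flat / nrm)[None, :], d)
    vals, vecs = _stc_spectrum(ensemble.matrix, basis)
    return STCResult(eigenvalues=vals, eigenvectors=vecs,
                     lag_frames=ensemble.lag_frames,
                     grid_shape=ensemble.grid_shape)


def bootstrap_significance(
    stimulus: StimulusMovie,
    spike_record: SpikeRecord,
    lag_frames: int = 6,
    n_boot: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
    spike_policy: str = "all",
    classifications=None,
    max_nested: int | None = None,
) -> STCResult:
    """Nested-bootstrap significance test of the STC spectrum.

    Each of ``n_boot`` surrogates circularly rotates all spike times by a
    uniform random offset (at least one lag window long), recomputes the STC
    spectrum under the same projection, and contributes one spectrum to the
    per-rank null distribution; the per-rank bounds are the ``alpha`` and
    ``1 - alpha`` surrogate percentiles (so under the null each rank escapes
    with probability ~2*alpha).  The returned result carries the first-pass
    spectrum and bounds.

    Significance is decided by nested testing of the spectrum's *extremes*:
    if the largest (or smallest) eigenvalue lies outside its rank's bounds
    it is significant; its eigenvector is projected out of the real and
    surrogate ensembles alike, the spectrum and its null are recomputed in
    the reduced space, and the new extremes re-tested — until neither
    escapes.  Testing only the extremes keeps the final set conservative:
    an interior eigenvalue becomes significant only by surfacing as an
    extreme once stronger subunits are removed.

    The rotation offset is quantized to whole frames so the per-frame spike
    multiplicity pattern (how many spikes share a frame) is preserved
    exactly; a fractional offset would split within-frame spike clumps
    across frame boundaries and make the surrogate spectra systematically
    narrower than the real one for strongly rate-modulated cells.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    lag_window_s = lag_frames * stimulus.frame_duration
    if stimulus.duration < 10 * lag_window_s:
        raise ValueError("recording shorter than 10x the lag window")
    rng = np.random.default_rng(seed)

    ensemble = build_ensemble(stimulus, spike_record, lag_frames,
                              spike_policy, classifications)
    W = _window_matrix(stimulus, lag_frames)
    eligible = _eligible_times(spike_record, spike_policy, classifications)
    all_times = np.concatenate(eligible)
    duration = stimulus.duration
    d = ensemble.dim

    sta = compute_sta(ensemble)
    sta_dir = sta.flat / np.linalg.norm(sta.flat)
    # whole-frame rotation offsets, at least one lag window away from zero
    frame_offsets = rng.integers(lag_frames, stimulus.n_frames - lag_frames,
                                 size=n_boot)
    offsets = frame_offsets * stimulus.frame_duration

    def surrogate_matrix(offset: float) -> np.ndarray:
        t = np.mod(all_times + offset, duration)
        f = np.floor(t / stimulus.frame_duration + 1e-9).astype(np.int64)
        f = f[(f >= lag_frames - 1) & (f < stimulus.n_frames)]
        return W[f - (lag_frames - 1)]

    removed = (np.empty((0, d)) if np.linalg.norm(sta.flat) == 0
               else sta_dir[None, :])
    significant_vecs: list[np.ndarray] = []
    first_pass: STCResult | None = None
    if max_nested is None:
        max_nested = d

    for _ in range(max_nested):
        basis = _complement_basis(removed, d)
        if basis.shape[1] == 0:
            break
        vals, vecs = _stc_spectrum(ensemble.matrix, basis)
        null = np.empty((n_boot, vals.size))
        for b, off in enumerate(offsets):
            null[b] = _stc_spectrum(surrogate_matrix(off), basis)[0]
        lo = np.percentile(null, 100 * alpha, axis=0)
        hi = np.percentile(null, 100 * (1 - alpha), axis=0)
        if first_pass is None:
            first_pass = STCResult(
                eigenvalues=vals, eigenvectors=vecs,
                lag_frames=lag_frames, grid_shape=stimulus.grid_shape,
                ci_lower=lo, ci_upper=hi, null_median=np.median(null, axis=0))
        new: list[np.ndarray] = []
        if vals[0] > hi[0]:
            new.append(vecs[0])
        if vals.size > 1 and vals[-1] < lo[-1]:
            new.append(vecs[-1])
        if not new:
            break
        significant_vecs.extend(new)
        removed = np.vstack([removed] + significant_vecs) if removed.size \
            else np.vstack(significant_vecs)

    # map the significant eigenvectors back to first-pass ranks, injectively
    significant_ranks: list[int] = []
    if significant_vecs:
        from scipy.optimize import linear_sum_assignment

        sim = np.abs(np.stack(significant_vecs) @ first_pass.eigenvectors.T)
        rows, cols = linear_sum_assignment(-sim)
        significant_ranks = [int(c) for c in cols]
    first_pass.significant_indices = sorted(significant_ranks)
    return first_pass


def sparse_sta(
    stimulus: StimulusMovie,
    spike_record: SpikeRecord,
    lag_frames: int = 4,
    spike_policy: str = "all",
    classifications=None,
) -> OnOffMaps:
    """Separate ON and OFF receptive-field maps from sparse noise.

    STA_ON averages indicator maps of bright flashes in the windows
    preceding each spike (STA_OFF likewise for dark flashes, *not*
    sign-flipped: both maps are response strength per pixel).  The uniform
    prior flash probability is subtracted so chance level is zero.  The
    overlap is the normalized dot product of the two spatial maps at their
    common peak lag, in percent; before the dot product each plane's median
    is subtracted — conditional flash probabilities sum to one, which
    otherwise leaves a negative pedestal on every map (the receptive field
    occupies a minority of the grid, so the median estimates that
    background level).
    """
    if stimulus.kind != "sparse":
        raise ValueError("sparse_sta requires a sparse-noise stimulus")
    ens = build_ensemble(stimulus, spike_record, lag_frames,
                         spike_policy, classifications)
    rows, cols = ens.grid_shape
    on_ind = (ens.matrix > 0).astype(np.float64)
    off_ind = (ens.matrix < 0).astype(np.float64)
    prior = 1.0 / (2 * rows * cols)  # uniform flash probability per pixel
    on_defined = bool(on_ind.sum() > 0)
    off_defined = bool(off_ind.sum() > 0)
    if not (on_defined and off_defined):
        logger.warning("one flash sign never preceded a spike; its map is undefined")
    sta_on = ens.reshape_filter(on_ind.mean(axis=0) - prior, kind="STA_ON")
    sta_off = ens.reshape_filter(off_ind.mean(axis=0) - prior, kind="STA_OFF")
    # background-corrected planes; common peak lag = most combined energy
    on_c = sta_on.weights - np.median(sta_on.weights, axis=(1, 2), keepdims=True)
    off_c = sta_off.weights - np.median(sta_off.weights, axis=(1, 2), keepdims=True)
    energy = (np.sum(on_c ** 2, axis=(1, 2)) + np.sum(off_c ** 2, axis=(1, 2)))
    lag = int(np.argmax(energy))
    a = on_c[lag].ravel()
    b = off_c[lag].ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    overlap = float(100.0 * (a @ b) / (na * nb)) if na > 0 and nb > 0 else np.nan
    return OnOffMaps(sta_on=sta_on, sta_off=sta_off,
                     overlap_percent=overlap, peak_lag=lag,
                     on_defined=on_defined, off_defined=off_defined)
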