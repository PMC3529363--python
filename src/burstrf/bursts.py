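"""Burst detection, ISI-shape clustering, and burst-aware spike bookkeeping.

Thalamic neurons fire two kinds of events: tonic spikes and all-or-none
calcium bursts.  Relay (LGN) bursts are brief and *decelerating* — two or
more spikes spaced <= 4 ms apart following >= 100 ms of silence.  Reticular
(PGN) bursts are long and *accelerating-decelerating* — at least 5 spikes
within 70 ms, spaced <= 30 ms apart, following >= 70 ms of silence, and
terminated when an inter-spike interval exceeds 30 ms.

Because every spike of a burst is initiated by the stimulus preceding the
burst's first (*cardinal*) spike, receptive-field estimation must not treat
later burst spikes as independent samples.  This module provides the
detection criteria, the 21-point shape-preserving ISI-curve representation
used to cluster burst shapes (Gaussian mixture, BIC-selected cluster count),
autocorrelogram width, per-spike group labelling by stimulus frame, and the
shift-correlation control that verifies one frame drives the whole burst.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

from burstrf.datatypes import SpikeRecord, StimulusMovie, SubunitFilter

logger = logging.getLogger(__name__)

__all__ = [
    "BurstEvent", "ISICurve", "ClusterResult", "SpikeClassification",
    "detect_bursts_lgn", "detect_bursts_pgn", "isi_curve", "cluster_bursts",
    "autocorr_width", "classify_spikes", "shift_correlation",
    "group_shift_stas", "is_u_shaped",
    "LABEL_TONIC", "LABEL_CARDINAL", "LABEL_GROUP_I_EXTRA",
    "LABEL_GROUP_II", "LABEL_GROUP_III", "LABEL_LATER",
]

# per-spike classification codes
LABEL_TONIC = 0
LABEL_CARDINAL = 1
LABEL_GROUP_I_EXTRA = 2   # same stimulus frame as the cardinal, not cardinal
LABEL_GROUP_II = 3        # second stimulus frame of the burst
LABEL_GROUP_III = 4       # third stimulus frame of the burst
LABEL_LATER = 5           # fourth frame onwards

N_ISI_POINTS = 21


@dataclass
class BurstEvent:
    """One detected burst: ascending spike times and their ISIs (ms)."""

    spike_times: np.ndarray
    source_criteria: str  # "lgn" | "pgn"

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=np.float64)

    @property
    def cardinal_time(self) -> float:
        return float(self.spike_times[0])

    @property
    def isis(self) -> np.ndarray:
        """Inter-spike intervals in milliseconds."""
        return np.diff(self.spike_times) * 1e3

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    @property
    def duration_ms(self) -> float:
        return float((self.spike_times[-1] - self.spike_times[0]) * 1e3)


@dataclass
class ISICurve:
    """A burst's ISI sequence resampled to 21 points (ms)."""

    values: np.ndarray
    n_source_spikes: int
    degenerate: bool = False  # single-ISI burst, constant curve


@dataclass
class ClusterResult:
    assignments: np.ndarray
    cluster_means: np.ndarray  # (n_clusters, 21)
    n_clusters: int
    model_score: float  # BIC of the selected mixture
    #: True where a burst is implausible under its own component (its
    #: Mahalanobis distance exceeds the 99% chi-square gate) — the
    #: mixture-model analogue of a spike-sorting noise cluster.  Such
    #: bursts keep their best-component assignment but should not be
    #: counted as members when cluster composition matters.
    outlier: np.ndarray = None

    def members(self, clusters) -> np.ndarray:
        """Boolean mask of non-outlier bursts assigned to ``clusters``."""
        mask = np.isin(self.assignments, clusters)
        if self.outlier is not None:
            mask &= ~self.outlier
        return mask


@dataclass
class SpikeClassification:
    """Per-spike labels and stimulus-frame offsets relative to the burst.

    ``labels`` uses the ``LABEL_*`` codes; ``frame_offset`` is the index of
    the stimulus frame containing the spike minus the frame containing the
    burst's cardinal spike (-1 for tonic spikes).
    """

    labels: np.ndarray
    frame_offset: np.ndarray
    spike_times: np.ndarray


def _check_sorted(spike_times: np.ndarray) -> np.ndarray:
    t = np.asarray(spike_times, dtype=np.float64)
    if t.ndim != 1:
        raise ValueError("spike_times must be 1-D")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly ascending")
    return t


def detect_bursts_lgn(spike_times: np.ndarray) -> list[BurstEvent]:
    """Relay-cell burst criterion: >=2 spikes, ISIs <= 4 ms, after >= 100 ms
    of silence.  The burst ends when an ISI exceeds 4 ms.  The first spike of
    the recording counts as following infinite silence.
    """
    return _detect_runs(spike_times, max_isi_s=4e-3, silence_s=100e-3,
                        min_spikes=2, criteria="lgn")


def detect_bursts_pgn(spike_times: np.ndarray) -> list[BurstEvent]:
    """Reticular-cell burst criterion: >=5 spikes within the first 70 ms,
    ISIs <= 30 ms, after >= 70 ms of silence; the event continues past 70 ms
    until an ISI exceeds 30 ms.
    """
    events = _detect_runs(spike_times, max_isi_s=30e-3, silence_s=70e-3,
                          min_spikes=5, criteria="pgn")
    kept = []
    for ev in events:
        in_window = ev.spike_times - ev.cardinal_time <= 70e-3 + 1e-12
        if int(np.count_nonzero(in_window)) >= 5:
            kept.append(ev)
    return kept


def _detect_runs(spike_times, max_isi_s, silence_s, min_spikes, criteria):
    t = _check_sorted(spike_times)
    bursts: list[BurstEvent] = []
    if t.size == 0:
        return bursts
    prev = np.concatenate([[-np.inf], t[:-1]])
    isi_next = np.diff(t)
    i = 0
    n = t.size
    while i < n:
        if t[i] - prev[i] >= silence_s:
            j = i
            while j < n - 1 and isi_next[j] <= max_isi_s:
                j += 1
            if j - i + 1 >= min_spikes:
                bursts.append(BurstEvent(t[i:j + 1], source_criteria=criteria))
            i = j + 1
        else:
            i += 1
    return bursts


def isi_curve(burst: BurstEvent, n_points: int = N_ISI_POINTS) -> ISICurve:
    """Resample a burst's ISI sequence to a fixed-length curve.

    The raw ISIs are placed on a uniform normalized index and upsampled with
    a shape-preserving (monotone piecewise-cubic, PCHIP) interpolant, so a
    U-shaped or monotone ISI sequence keeps its shape without overshoot and
    every burst maps to a point in the same ``n_points``-dimensional space.
    A single-ISI burst yields a constant curve, flagged ``degenerate``.
    """
    isis = burst.isis
    if isis.size == 0:
        raise ValueError("burst has fewer than 2 spikes")
    if isis.size == 1:
        return ISICurve(values=np.full(n_points, isis[0]),
                        n_source_spikes=burst.n_spikes, degenerate=True)
    x = np.linspace(0.0, 1.0, isis.size)
    xi = np.linspace(0.0, 1.0, n_points)
    values = PchipInterpolator(x, isis)(xi)
    return ISICurve(values=values, n_source_spikes=burst.n_spikes)


def cluster_bursts(
    curves: list[ISICurve],
    max_clusters: int = 5,
    seed: int = 0,
    covariance_type: str = "diag",
    outlier_quantile: float = 0.99,
) -> ClusterResult:
    """Cluster ISI curves with a Gaussian mixture in 21-D ISI-shape space.

    The number of components is chosen by BIC over 1..max_clusters.
    Diagonal covariances by default: with a few hundred bursts the BIC
    penalty of a full 21-D covariance (~250 parameters per component)
    swamps the likelihood gain and even well-separated shape clusters
    collapse to one component.  Identical curves collapse to one cluster.

    Bursts whose squared Mahalanobis distance to their own component
    exceeds the ``outlier_quantile`` chi-square gate are flagged in
    ``ClusterResult.outlier`` (they keep their best-component assignment);
    cluster means are computed over inliers.
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves to cluster")
    X = np.stack([c.values for c in curves])
    kmax = min(max_clusters, len(curves))
    if kmax < max_clusters:
        logger.warning("reducing max_clusters from %d to %d (only %d curves)",
                       max_clusters, kmax, len(curves))
    # degenerate duplicated data: a singular mixture; short-circuit
    if np.allclose(X, X[0]):
        return ClusterResult(assignments=np.zeros(len(curves), dtype=int),
                             cluster_means=X[:1].copy(), n_clusters=1,
                             model_score=np.nan,
                             outlier=np.zeros(len(curves), dtype=bool))
    best = None
    for k in range(1, kmax + 1):
        gm = GaussianMixture(n_components=k, covariance_type=covariance_type,
                             n_init=3, reg_covar=1e-4, random_state=seed)
        gm.fit(X)
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    assignments = gm.predict(X)
    outlier = _mahalanobis_sq(X, gm, assignments) > chi2.ppf(
        outlier_quantile, X.shape[1])
    means = np.stack([
        X[(assignments == c) & ~outlier].mean(axis=0)
        if np.any((assignments == c) & ~outlier) else gm.means_[c]
        for c in range(k)
    ])
    return ClusterResult(assignments=assignments, cluster_means=means,
                         n_clusters=k, model_score=float(bic),
                         outlier=outlier)


def _mahalanobis_sq(X: np.ndarray, gm: GaussianMixture,
                    assignments: np.ndarray) -> np.ndarray:
    d = np.empty(X.shape[0])
    for c in range(gm.n_components):
        mask = assignments == c
        if not np.any(mask):
            continue
        diff = X[mask] - gm.means_[c]
        if gm.covariance_type == "diag":
            d[mask] = np.sum(diff ** 2 / gm.covariances_[c], axis=1)
        elif gm.covariance_type == "full":
            inv = np.linalg.inv(gm.covariances_[c])
            d[mask] = np.einsum("ij,jk,ik->i", diff, inv, diff)
        elif gm.covariance_type == "spherical":
            d[mask] = np.sum(diff ** 2, axis=1) / gm.covariances_[c]
        else:  # tied
            inv = np.linalg.inv(gm.covariances_)
            d[mask] = np.einsum("ij,jk,ik->i", diff, inv, diff)
    return d


def is_u_shaped(curve: np.ndarray, depth: float = 0.5) -> bool:
    """Whether an ISI curve has the accelerating-decelerating (U) shape.

    Reticular bursts accelerate then decelerate: the inter-spike interval
    drops several-fold before growing again.  A curve counts as U-shaped
    when its minimum falls in the middle third of the burst and is less
    than ``depth`` times *both* boundary intervals — a shallow central
    wiggle does not qualify.
    """
    curve = np.asarray(curve, dtype=np.float64)
    k = int(np.argmin(curve))
    n = curve.size
    return (n // 3 <= k < n - n // 3
            and curve[k] < depth * curve[0]
            and curve[k] < depth * curve[-1])


def autocorr_width(
    spike_times: np.ndarray,
    bin_ms: float = 1.0,
    max_lag_ms: float = 100.0,
    threshold_frac: float = 0.05,
) -> float:
    """Width (ms) of the spike-train autocorrelogram at 5% of peak height.

    The correlogram is built from all spike-pair lags within
    ``(0, max_lag_ms]`` (zero-lag bin excluded, symmetric by construction).
    The width is the full extent (across zero lag) of the contiguous
    region, containing the peak bin, whose counts exceed ``threshold_frac``
    of the peak; the refractory gap right at zero lag is bridged.  An empty
    correlogram yields one bin width.
    """
    t = _check_sorted(spike_times)
    if t.size < 2:
        raise ValueError("need at least 2 spikes")
    max_lag_s = max_lag_ms * 1e-3
    n_bins = int(round(max_lag_ms / bin_ms))
    counts = np.zeros(n_bins)
    # pair counting restricted to the lag window
    hi = np.searchsorted(t, t + max_lag_s, side="right")
    for i in range(t.size):
        lags = t[i + 1:hi[i]] - t[i]
        if lags.size:
            idx = np.minimum((lags / (bin_ms * 1e-3)).astype(int), n_bins - 1)
            np.add.at(counts, idx, 1)
    if counts.max() == 0:
        return bin_ms  # empty correlogram: central bin only
    thresh = threshold_frac * counts.max()
    peak = int(np.argmax(counts))
    hi = peak
    while hi < n_bins - 1 and counts[hi + 1] > thresh:
        hi += 1
    return (2 * hi + 1) * bin_ms


def classify_spikes(
    spike_times: np.ndarray,
    bursts: list[BurstEvent],
    frame_duration: float,
) -> SpikeClassification:
    """Label each spike by the stimulus frame it falls in, relative to the
    frame containing its burst's cardinal spike.

    Spikes in the cardinal's frame form Group I (the cardinal itself plus
    ``GROUP_I_EXTRA`` companions), spikes one frame later Group II, two
    frames later Group III, anything beyond ``LATER``.  Non-burst spikes are
    tonic.
    """
    t = _check_sorted(spike_times)
    labels = np.full(t.size, LABEL_TONIC, dtype=np.int64)
    offsets = np.full(t.size, -1, dtype=np.int64)
    frame = np.floor(t / frame_duration).astype(np.int64)
    offset_to_label = {0: LABEL_GROUP_I_EXTRA, 1: LABEL_GROUP_II,
                       2: LABEL_GROUP_III}
    for burst in bursts:
        f0 = int(np.floor(burst.cardinal_time / frame_duration))
        idx = np.searchsorted(t, burst.spike_times)
        for pos, i in enumerate(idx):
            off = int(frame[i] - f0)
            offsets[i] = off
            if pos == 0:
                labels[i] = LABEL_CARDINAL
            else:
                labels[i] = offset_to_label.get(off, LABEL_LATER)
    return SpikeClassification(labels=labels, frame_offset=offsets,
                               spike_times=t)


def group_shift_stas(
    stimulus: StimulusMovie,
    classification: SpikeClassification,
    lag_frames: int,
    groups: tuple[int, ...] = (1, 2, 3),
    shifts: tuple[int, ...] = (0, 1, 2),
) -> dict[tuple[int, int], SubunitFilter]:
    """STAs per (burst group, temporal shift) for the burst-independence control.

    For group *g*, one spike per burst (the first spike whose frame offset is
    ``g - 1``) is used, so each burst contributes equally.  A shift of *s*
    advances the triggering window *s* frames back in time; if one stimulus
    frame drives the whole burst, the Group II STA at Shift_1 and Group III
    STA at Shift_2 should match the Group I STA at Shift_0.
    """
    t = classification.spike_times
    frame = np.floor(t / stimulus.frame_duration).astype(np.int64)
    # first spike per burst per group
    group_frames: dict[int, list[int]] = {g: [] for g in groups}
    i = 0
    n = t.size
    while i < n:
        if classification.labels[i] == LABEL_CARDINAL:
            j = i
            seen: set[int] = set()
            while j < n and (classification.labels[j] != LABEL_TONIC) and \
                    (j == i or classification.labels[j] != LABEL_CARDINAL):
                off = int(classification.frame_offset[j])
                g = off + 1
                if g in group_frames and g not in seen:
                    group_frames[g].append(int(frame[j]))
                    seen.add(g)
                j += 1
            i = j
        else:
            i += 1
    flat = stimulus.frames.reshape(stimulus.n_frames, -1)
    rows, cols = stimulus.grid_shape
    out: dict[tuple[int, int], SubunitFilter] = {}
    for g in groups:
        frames_g = np.asarray(group_frames[g], dtype=np.int64)
        for s in shifts:
            end = frames_g - s
            valid = end >= lag_frames - 1
            if not np.any(valid):
                continue
            idx = end[valid]
            windows = np.stack([flat[f - lag_frames + 1: f + 1] for f in idx])
            sta = windows.mean(axis=0).reshape(lag_frames, rows, cols)
            out[(g, s)] = SubunitFilter(weights=sta, kind="STA")
    return out


def shift_correlation(
    stas: dict[tuple[int, int], SubunitFilter],
    reference: tuple[int, int] = (1, 0),
) -> dict[tuple[int, int], float]:
    """Normalized dot products of each (group, shift) STA against the
    Group I / Shift_0 STA; the reference's self-correlation is 1 by
    construction."""
    if reference not in stas:
        raise ValueError("reference STA missing from the table")
    ref = stas[reference].flat
    shape = stas[reference].weights.shape
    ref_norm = np.linalg.norm(ref)
    if ref_norm == 0:
        raise ValueError("reference STA has zero norm")
    table: dict[tuple[int, int], float] = {}
    for key, f in stas.items():
        if f.weights.shape != shape:
            raise ValueError(f"STA {key} shape mismatch")
        nrm = np.linalg.norm(f.flat)
        table[key] = float(f.flat @ ref / (nrm * ref_norm)) if nrm else np.nan
    return table


def bursts_from_record(record: SpikeRecord, criteria: str,
                       repeat: int = 0) -> list[BurstEvent]:
    """Convenience: run the chosen detector on one repeat of a record."""
    detect = detect_bursts_lgn if criteria == "lgn" else detect_bursts_pgn
    return detect(record.repeats[repeat])
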