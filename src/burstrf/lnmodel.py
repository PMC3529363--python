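"""Linear-nonlinear (LN) cascade models with binned, cross-validated
nonlinearities.

The linear stage is the dot product between a receptive-field subunit and
the trailing stimulus window at each frame, normalized so +1/-1 mark maximal
same/opposite-sign similarity over the series.  The nonlinear stage maps the
filter output to a firing rate by binning the output range [-1, 1] and
taking the mean trial-averaged spike count (PSTH) in each bin — a lookup
table estimated directly from data.  1D models use the STA alone; 2D models
add one STC subunit and a joint two-dimensional nonlinearity.

:class:`LNModel1D` and :class:`LNModel2D` follow the scikit-learn estimator
protocol (``fit``/``predict``, ``get_params``/``set_params``, fitted
attributes with trailing underscores), so they compose with sklearn model
selection; the module-level functions are thin functional wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from burstrf.datatypes import SpikeRecord, StimulusMovie, SubunitFilter

logger = logging.getLogger(__name__)

__all__ = [
    "FilterOutputSeries", "PSTH", "Nonlinearity1D", "Nonlinearity2D",
    "filter_output", "compute_psth",
    "estimate_nonlinearity_1d", "estimate_nonlinearity_2d",
    "optimize_bins", "LNModel1D", "LNModel2D",
]


@dataclass
class FilterOutputSeries:
    """Per-frame filter output, normalized to [-1, 1].

    ``norm`` is the absolute global maximum the raw dot products were
    divided by (kept so test data can be scaled consistently with the
    training data).
    """

    values: np.ndarray
    norm: float
    filter_kind: str = ""


@dataclass
class PSTH:
    """Trial-averaged response to a frozen stimulus.

    ``counts`` is (n_repeats, n_frames) spike counts per frame bin;
    ``rate`` the across-repeat mean (spikes per frame).
    """

    counts: np.ndarray
    frame_duration: float

    @property
    def rate(self) -> np.ndarray:
        return self.counts.mean(axis=0)

    @property
    def n_repeats(self) -> int:
        return self.counts.shape[0]

    @property
    def n_frames(self) -> int:
        return self.counts.shape[1]

    def slice(self, sl: slice) -> "PSTH":
        return PSTH(counts=self.counts[:, sl], frame_duration=self.frame_duration)


@dataclass
class Nonlinearity1D:
    """Binned response nonlinearity over the filter-output range [-1, 1]."""

    bin_edges: np.ndarray
    mean_rate: np.ndarray      # NaN where the bin is empty
    occupancy: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.mean_rate.size

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0


@dataclass
class Nonlinearity2D:
    """Joint response nonlinearity over two filter outputs."""

    bin_edges_x: np.ndarray
    bin_edges_y: np.ndarray
    mean_rate: np.ndarray      # (nx, ny), NaN where empty
    occupancy: np.ndarray

    @property
    def occupied(self) -> np.ndarray:
        return self.occupancy > 0


def filter_output(
    stimulus: StimulusMovie,
    filt: SubunitFilter,
    norm: float | None = None,
) -> FilterOutputSeries:
    """Dot product of the trailing stimulus window with the filter, per frame.

    Frames earlier than the filter length get output 0.  The series is
    divided by its absolute global maximum (or by ``norm`` if given, e.g.
    the maximum of the training series).
    """
    flat_w = filt.flat
    if not np.any(flat_w):
        raise ValueError("all-zero filter")
    n_lags = filt.n_lags
    if n_lags > stimulus.n_frames:
        raise ValueError("filter has more lags than the stimulus has frames")
    flat = stimulus.frames.reshape(stimulus.n_frames, -1)
    w = filt.weights.reshape(n_lags, -1)
    out = np.zeros(stimulus.n_frames)
    for lag in range(n_lags):
        contrib = flat @ w[lag]
        shift = n_lags - 1 - lag
        if shift:
            out[shift:] += contrib[:-shift]
        else:
            out += contrib
    out[: n_lags - 1] = 0.0
    if norm is None:
        norm = float(np.max(np.abs(out)))
        if norm == 0:
            raise ValueError("filter output is identically zero")
    return FilterOutputSeries(values=out / norm, norm=norm,
                              filter_kind=filt.kind)


def compute_psth(
    spike_record: SpikeRecord,
    n_frames: int,
    frame_duration: float,
) -> PSTH:
    """Per-frame spike counts for every repeat, plus their mean."""
    if spike_record.n_repeats < 1:
        raise ValueError("need at least one repeat")
    counts = np.zeros((spike_record.n_repeats, n_frames))
    for j, times in enumerate(spike_record.repeats):
        f = np.floor(times / frame_duration).astype(np.int64)
        f = f[(f >= 0) & (f < n_frames)]
        np.add.at(counts[j], f, 1.0)
    return PSTH(counts=counts, frame_duration=frame_duration)


def _bin_index(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, edges.size - 2)


def estimate_nonlinearity_1d(
    output: FilterOutputSeries | np.ndarray,
    psth: PSTH | np.ndarray,
    n_bins: int = 10,
) -> Nonlinearity1D:
    """Mean PSTH rate in each filter-output bin over [-1, 1].

    Empty bins are flagged with NaN mean rate and zero occupancy, never
    silently interpolated.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    v = output.values if isinstance(output, FilterOutputSeries) else np.asarray(output)
    r = psth.rate if isinstance(psth, PSTH) else np.asarray(psth)
    if v.shape != r.shape:
        raise ValueError("filter output and PSTH must have equal length")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    idx = _bin_index(v, edges)
    occupancy = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=r, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_rate = np.where(occupancy > 0, sums / np.maximum(occupancy, 1), np.nan)
    return Nonlinearity1D(bin_edges=edges, mean_rate=mean_rate,
                          occupancy=occupancy)


def estimate_nonlinearity_2d(
    out_a: FilterOutputSeries | np.ndarray,
    out_b: FilterOutputSeries | np.ndarray,
    psth: PSTH | np.ndarray,
    n_bins: int = 10,
) -> Nonlinearity2D:
    """Mean PSTH rate in each joint (output_a, output_b) bin."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    a = out_a.values if isinstance(out_a, FilterOutputSeries) else np.asarray(out_a)
    b = out_b.values if isinstance(out_b, FilterOutputSeries) else np.asarray(out_b)
    r = psth.rate if isinstance(psth, PSTH) else np.asarray(psth)
    if not (a.shape == b.shape == r.shape):
        raise ValueError("outputs and PSTH must have equal length")
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    ia, ib = _bin_index(a, edges), _bin_index(b, edges)
    flat = ia * n_bins + ib
    occupancy = np.bincount(flat, minlength=n_bins * n_bins).astype(float)
    sums = np.bincount(flat, weights=r, minlength=n_bins * n_bins)
    with np.errstate(invalid="ignore"):
        mean_rate = np.where(occupancy > 0, sums / np.maximum(occupancy, 1), np.nan)
    return Nonlinearity2D(
        bin_edges_x=edges, bin_edges_y=edges,
        mean_rate=mean_rate.reshape(n_bins, n_bins),
        occupancy=occupancy.reshape(n_bins, n_bins))


def _lookup_1d(nl: Nonlinearity1D, values: np.ndarray) -> np.ndarray:
    """Bin lookup with nearest-occupied-bin fallback for empty bins."""
    idx = _bin_index(values, nl.bin_edges)
    occ = np.flatnonzero(nl.occupied)
    if occ.size == 0:
        raise ValueError("nonlinearity has no occupied bins")
    empty = ~nl.occupied[idx]
    if np.any(empty):
        nearest = occ[np.argmin(np.abs(idx[empty][:, None] - occ[None, :]), axis=1)]
        idx = idx.copy()
        idx[empty] = nearest
    return nl.mean_rate[idx]


def _lookup_2d(nl: Nonlinearity2D, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ia = _bin_index(a, nl.bin_edges_x)
    ib = _bin_index(b, nl.bin_edges_y)
    occ = np.argwhere(nl.occupied)
    if occ.size == 0:
        raise ValueError("nonlinearity has no occupied bins")
    rate = np.empty(a.size)
    ok = nl.occupied[ia, ib]
    rate[ok] = nl.mean_rate[ia[ok], ib[ok]]
    if np.any(~ok):
        bad = np.flatnonzero(~ok)
        d = ((ia[bad][:, None] - occ[None, :, 0]) ** 2
             + (ib[bad][:, None] - occ[None, :, 1]) ** 2)
        nearest = occ[np.argmin(d, axis=1)]
        rate[bad] = nl.mean_rate[nearest[:, 0], nearest[:, 1]]
    return rate


def _naive_ev(rate: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((rate - rate.mean()) ** 2))
    if sst == 0:
        return np.nan
    return 1.0 - float(np.sum((rate - pred) ** 2)) / sst


def optimize_bins(
    outputs_train,
    psth_train: PSTH,
    outputs_test,
    psth_test: PSTH,
    start: int = 4,
    step: int = 2,
    max_bins: int = 30,
) -> int:
    """Cross-validated bin-count search for the nonlinearity.

    Starting at ``start`` bins and stepping by ``step``, the nonlinearity is
    fit on the training half and scored (explained variance) on the test
    half; the search halts when increasing the bin count reduces test
    performance and returns the last improving value.  ``outputs_*`` is a
    single filter-output series (1D model) or a pair (2D model).
    """
    pair = isinstance(outputs_train, (tuple, list))

    def score(n_bins: int) -> float:
        if pair:
            nl = estimate_nonlinearity_2d(*outputs_train, psth_train, n_bins)
            a = outputs_test[0].values if isinstance(outputs_test[0], FilterOutputSeries) else outputs_test[0]
            b = outputs_test[1].values if isinstance(outputs_test[1], FilterOutputSeries) else outputs_test[1]
            pred = _lookup_2d(nl, np.clip(a, -1, 1), np.clip(b, -1, 1))
        else:
            nl = estimate_nonlinearity_1d(outputs_train, psth_train, n_bins)
            v = outputs_test.values if isinstance(outputs_test, FilterOutputSeries) else outputs_test
            pred = _lookup_1d(nl, np.clip(v, -1, 1))
        return _naive_ev(psth_test.rate, pred)

    best_bins = start
    best_score = score(start)
    n = start + step
    while n <= max_bins:
        s = score(n)
        if not np.isnan(s) and (np.isnan(best_score) or s > best_score):
            best_bins, best_score = n, s
        else:
            break
        n += step
    return best_bins


class LNModel1D(BaseEstimator):
    """One-subunit LN model: filter -> binned nonlinearity -> rate.

    Parameters
    ----------
    filt
        The linear subunit (typically the STA estimated on training data).
    n_bins
        Bin count for the nonlinearity over [-1, 1].

    Fitted attributes
    -----------------
    nonlinearity_ : Nonlinearity1D
    norm_ : float
        Training-series output normalisation, reused at prediction time.
    n_free_params_ : int
        Number of occupied nonlinearity bins.
    """

    def __init__(self, filt: SubunitFilter = None, n_bins: int = 10):
        self.filt = filt
        self.n_bins = n_bins

    def fit(self, stimulus: StimulusMovie, psth: PSTH) -> "LNModel1D":
        out = filter_output(stimulus, self.filt)
        self.norm_ = out.norm
        self.nonlinearity_ = estimate_nonlinearity_1d(out, psth, self.n_bins)
        self.n_free_params_ = int(np.count_nonzero(self.nonlinearity_.occupied))
        return self

    def predict(self, stimulus: StimulusMovie) -> np.ndarray:
        out = filter_output(stimulus, self.filt, norm=self.norm_)
        return _lookup_1d(self.nonlinearity_, np.clip(out.values, -1, 1))


class LNModel2D(BaseEstimator):
    """Two-subunit LN model (STA + one STC subunit, joint nonlinearity)."""

    def __init__(self, filt_a: SubunitFilter = None,
                 filt_b: SubunitFilter = None, n_bins: int = 10):
        self.filt_a = filt_a
        self.filt_b = filt_b
        self.n_bins = n_bins

    def fit(self, stimulus: StimulusMovie, psth: PSTH) -> "LNModel2D":
        out_a = filter_output(stimulus, self.filt_a)
        out_b = filter_output(stimulus, self.filt_b)
        self.norm_a_ = out_a.norm
        self.norm_b_ = out_b.norm
        self.nonlinearity_ = estimate_nonlinearity_2d(out_a, out_b, psth,
                                                      self.n_bins)
        self.n_free_params_ = int(np.count_nonzero(self.nonlinearity_.occupied))
        return self

    def predict(self, stimulus: StimulusMovie) -> np.ndarray:
        a = filter_output(stimulus, self.filt_a, norm=self.norm_a_).values
        b = filter_output(stimulus, self.filt_b, norm=self.norm_b_).values
        return _lookup_2d(self.nonlinearity_, np.clip(a, -1, 1),
                          np.clip(b, -1, 1))
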