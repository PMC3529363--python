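"""Model-performance and information metrics.

Two explained-variance estimators quantify how much of the stimulus-driven
response variance a model prediction captures:

* a bias-corrected estimator that accounts for the finite number of
  repeats (through the noise variance of the trial-mean response) and for
  the model's free parameters;
* a signal-power estimator that separates stimulus-locked (signal) from
  trial-to-trial (noise) response power and asks what fraction of the
  signal power the prediction explains.

Mutual information (bits/spike) carried by a subunit is the Kullback-Leibler
divergence between the distribution of its filter output just before spikes
and the distribution over the whole stimulus.  Finite sampling inflates the
estimate, so the same quantity computed for the *most non-significant*
subunit — which by construction carries no stimulus information — is
subtracted as a bias term; estimates are averaged over the bin-size range
where they are stable (0.15-0.4 prior SDs), with the SD over that range as
the statistical error.  Synergy compares the joint two-subunit information
with the sum of the individual ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from burstrf.lnmodel import PSTH, FilterOutputSeries

logger = logging.getLogger(__name__)

__all__ = [
    "VarianceExplained", "InfoEstimate", "SynergyIndex",
    "explained_variance_corrected", "explained_variance_signal_power",
    "mutual_info_1d", "mutual_info_2d", "synergy",
]

#: Bin sizes (multiples of the prior SD) scanned by the information
#: estimators, and the sub-range over which the corrected estimate is
#: averaged.
DEFAULT_BIN_SIZE_GRID = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 4)
STABLE_RANGE = (0.15, 0.4)


@dataclass
class VarianceExplained:
    """Bias-corrected explained variance and its ingredients."""

    gamma_corrected: float
    gamma_naive: float
    sigma2: float
    N: int
    R: int
    n_free_params: int
    corrected: bool = True  # False when the R>=2 correction was unavailable

    @property
    def N_sigma(self) -> int:
        return self.N * (self.R - 1)


@dataclass
class InfoEstimate:
    """Bias-corrected mutual information of one subunit (or pair), bits/spike."""

    value: float
    error: float          # SD over the stable bin-size range
    bin_sizes: np.ndarray
    raw: np.ndarray       # uncorrected KL per bin size
    bias: np.ndarray      # bias term per bin size
    stable_mask: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    @property
    def corrected(self) -> np.ndarray:
        return self.raw - self.bias


@dataclass
class SynergyIndex:
    """i_joint - (i_sta + i_stc): >0 synergy, <0 redundancy, ~0 independence."""

    value: float


def explained_variance_corrected(
    psth: PSTH,
    prediction: np.ndarray,
    n_free_params: int = 0,
) -> VarianceExplained:
    """Explained variance corrected for finite repeats and free parameters.

    With per-repeat responses d_ij (i = 1..N frames, j = 1..R repeats),
    trial mean d̄_i, model prediction m_i and noise variance of the trial
    mean sigma^2 = sum_ij (d_ij - d̄_i)^2 / (R N (R-1)), the estimator is::

        gamma = 1 - [SSE/sigma^2 - (N-n) Ns/(Ns-2)]
                    / [SST/sigma^2 - (N-1) Ns/(Ns-2)]

    with Ns = N(R-1), SSE = sum_i (d̄_i - m_i)^2 and
    SST = sum_i (d̄_i - mean(d̄))^2.  The Ns/(Ns-2) factor compensates for
    sigma^2 being itself estimated.  With one repeat (or noise-free
    repeats), the correction is unavailable and the naive ratio
    1 - SSE/SST is returned, flagged.
    """
    prediction = np.asarray(prediction, dtype=np.float64)
    d_bar = psth.rate
    if prediction.shape != d_bar.shape:
        raise ValueError("prediction and PSTH must have equal length")
    N = psth.n_frames
    R = psth.n_repeats
    sse = float(np.sum((d_bar - prediction) ** 2))
    sst = float(np.sum((d_bar - d_bar.mean()) ** 2))
    if sst == 0:
        raise ValueError("response has zero variance")
    naive = 1.0 - sse / sst
    if R < 2:
        logger.warning("single repeat: falling back to uncorrected explained variance")
        return VarianceExplained(gamma_corrected=naive, gamma_naive=naive,
                                 sigma2=np.nan, N=N, R=R,
                                 n_free_params=n_free_params, corrected=False)
    sigma2 = float(np.sum((psth.counts - d_bar) ** 2) / (R * N * (R - 1)))
    n_sigma = N * (R - 1)
    if sigma2 == 0 or n_sigma <= 2:
        return VarianceExplained(gamma_corrected=naive, gamma_naive=naive,
                                 sigma2=sigma2, N=N, R=R,
                                 n_free_params=n_free_params, corrected=False)
    shrink = n_sigma / (n_sigma - 2)
    num = sse / sigma2 - (N - n_free_params) * shrink
    den = sst / sigma2 - (N - 1) * shrink
    if den <= 0:
        raise ValueError("response variance does not exceed the noise floor")
    return VarianceExplained(gamma_corrected=1.0 - num / den,
                             gamma_naive=naive, sigma2=sigma2, N=N, R=R,
                             n_free_params=n_free_params)


def explained_variance_signal_power(psth: PSTH, prediction: np.ndarray) -> float:
    """Explained fraction of the stimulus-locked (signal) response power.

    The signal power is estimated from across-repeat covariance:
    P_signal = (R * var_t(d̄) - mean_j var_t(d_j)) / (R - 1).  The residual
    power of the prediction, after subtracting the sampling noise left in
    the trial mean (P_noise / R), is compared against it:
    1 - (MSE - P_noise/R) / P_signal.
    """
    prediction = np.asarray(prediction, dtype=np.float64)
    if psth.n_repeats < 2:
        raise ValueError("signal-power estimator needs >= 2 repeats")
    d_bar = psth.rate
    if prediction.shape != d_bar.shape:
        raise ValueError("prediction and PSTH must have equal length")
    p_mean = float(np.var(d_bar))
    p_resp = float(np.mean(np.var(psth.counts, axis=1)))
    R = psth.n_repeats
    p_signal = (R * p_mean - p_resp) / (R - 1)
    if p_signal <= 0:
        raise ValueError("non-positive signal-power estimate")
    p_noise = p_resp - p_signal
    mse = float(np.mean((d_bar - prediction) ** 2))
    return 1.0 - (mse - p_noise / R) / p_signal


def _values(x) -> np.ndarray:
    return x.values if isinstance(x, FilterOutputSeries) else np.asarray(x, float)


def _kl_binned(prior: np.ndarray, cond: np.ndarray, bin_width: float) -> float:
    """KL(cond || prior) in bits from histograms with the given bin width.

    Conditional samples are a subsample of the prior in this pipeline, so
    every occupied conditional bin has prior mass; any conditional mass that
    nevertheless lands on an empty prior bin (externally supplied
    distributions) is merged into the nearest occupied prior bin.
    """
    lo = min(prior.min(), cond.min())
    hi = max(prior.max(), cond.max())
    n_bins = max(int(np.ceil((hi - lo) / bin_width)), 1)
    edges = lo + np.arange(n_bins + 1) * bin_width
    p, _ = np.histogram(prior, bins=edges)
    q, _ = np.histogram(cond, bins=edges)
    p = p.astype(float) / p.sum()
    q = q.astype(float) / q.sum()
    bad = (q > 0) & (p == 0)
    if np.any(bad):
        good = np.flatnonzero(p > 0)
        for i in np.flatnonzero(bad):
            j = good[np.argmin(np.abs(good - i))]
            q[j] += q[i]
            q[i] = 0.0
    mask = q > 0
    return float(np.sum(q[mask] * np.log2(q[mask] / p[mask])))


def _kl_binned_2d(prior_a, prior_b, cond_a, cond_b, wa: float, wb: float) -> float:
    """Joint 2-D KL(cond || prior) in bits."""
    def edges(x, y, w):
        lo = min(x.min(), y.min())
        hi = max(x.max(), y.max())
        n = max(int(np.ceil((hi - lo) / w)), 1)
        return lo + np.arange(n + 1) * w

    ea = edges(prior_a, cond_a, wa)
    eb = edges(prior_b, cond_b, wb)
    p, _, _ = np.histogram2d(prior_a, prior_b, bins=(ea, eb))
    q, _, _ = np.histogram2d(cond_a, cond_b, bins=(ea, eb))
    p = p / p.sum()
    q = q / q.sum()
    valid = (q > 0) & (p > 0)
    total = float(np.sum(q[valid] * np.log2(q[valid] / p[valid])))
    stray = float(q[(q > 0) & (p == 0)].sum())
    if stray > 0:
        # merge stray conditional mass into the best-supported prior bin
        total += stray * np.log2(stray / p[p > 0].max())
    return total


def _stable_stats(bin_sizes, corrected, stable_range):
    mask = (bin_sizes >= stable_range[0] - 1e-12) & (bin_sizes <= stable_range[1] + 1e-12)
    if not np.any(mask):
        mask = np.ones_like(bin_sizes, dtype=bool)
    return float(np.mean(corrected[mask])), float(np.std(corrected[mask])), mask


def mutual_info_1d(
    output,
    spike_frames: np.ndarray,
    bin_size_grid: np.ndarray | None = None,
    nonsig_output=None,
    stable_range: tuple[float, float] = STABLE_RANGE,
) -> InfoEstimate:
    """Mutual information carried by one subunit's filter output, bits/spike.

    ``output`` is the per-frame filter output; ``spike_frames`` the frame
    indices of spikes (with multiplicity).  Bin sizes are multiples of the
    prior's SD.  ``nonsig_output`` (the output of the most non-significant
    subunit) provides the finite-sampling bias, computed identically and
    subtracted; without it the raw (biased) estimate is returned.
    """
    v = _values(output)
    spike_frames = np.asarray(spike_frames, dtype=np.int64)
    if spike_frames.size == 0:
        raise ValueError("no spikes")
    if bin_size_grid is None:
        bin_size_grid = DEFAULT_BIN_SIZE_GRID
    bin_size_grid = np.asarray(bin_size_grid, float)
    cond = v[spike_frames]
    sd = float(np.std(v))
    if sd == 0:
        raise ValueError("filter output has zero variance")
    raw = np.array([_kl_binned(v, cond, h * sd) for h in bin_size_grid])
    if nonsig_output is not None:
        nv = _values(nonsig_output)
        ncond = nv[spike_frames]
        nsd = float(np.std(nv))
        bias = np.array([_kl_binned(nv, ncond, h * nsd) for h in bin_size_grid])
    else:
        bias = np.zeros_like(raw)
    corrected = raw - bias
    n_cond_bins = max(int(np.ceil((v.max() - v.min()) / (bin_size_grid[0] * sd))), 1)
    if cond.size < 10 * n_cond_bins:
        logger.warning("spike-conditional sample (%d) is small for the finest "
                       "bin grid (%d bins)", cond.size, n_cond_bins)
    value, error, mask = _stable_stats(bin_size_grid, corrected, stable_range)
    return InfoEstimate(value=value, error=error, bin_sizes=bin_size_grid,
                        raw=raw, bias=bias, stable_mask=mask)


def mutual_info_2d(
    output_a,
    output_b,
    spike_frames: np.ndarray,
    bin_size_grid: np.ndarray | None = None,
    nonsig_output=None,
    stable_range: tuple[float, float] = STABLE_RANGE,
) -> InfoEstimate:
    """Joint mutual information of two subunits, bits/spike.

    The 2-D bias is estimated as I(a, nonsig) - I(a): the extra information
    that merely adding an uninformative dimension appears to contribute.
    """
    a, b = _values(output_a), _values(output_b)
    spike_frames = np.asarray(spike_frames, dtype=np.int64)
    if spike_frames.size == 0:
        raise ValueError("no spikes")
    if bin_size_grid is None:
        bin_size_grid = DEFAULT_BIN_SIZE_GRID
    bin_size_grid = np.asarray(bin_size_grid, float)
    ca, cb = a[spike_frames], b[spike_frames]
    sa, sb = float(np.std(a)), float(np.std(b))
    if sa == 0 or sb == 0:
        raise ValueError("filter output has zero variance")
    raw = np.array([_kl_binned_2d(a, b, ca, cb, h * sa, h * sb)
                    for h in bin_size_grid])
    if nonsig_output is not None:
        nv = _values(nonsig_output)
        ncond = nv[spike_frames]
        nsd = float(np.std(nv))
        bias = np.array([
            _kl_binned_2d(a, nv, ca, ncond, h * sa, h * nsd)
            - _kl_binned(a, ca, h * sa)
            for h in bin_size_grid
        ])
    else:
        bias = np.zeros_like(raw)
    corrected = raw - bias
    value, error, mask = _stable_stats(bin_size_grid, corrected, stable_range)
    return InfoEstimate(value=value, error=error, bin_sizes=bin_size_grid,
                        raw=raw, bias=bias, stable_mask=mask)


def synergy(i_joint: float | InfoEstimate,
            i_sta: float | InfoEstimate,
            i_stc: float | InfoEstimate) -> SynergyIndex:
    """Synergy index: i_joint - (i_sta + i_stc)."""
    def val(x):
        return x.value if isinstance(x, InfoEstimate) else float(x)
    return SynergyIndex(value=val(i_joint) - (val(i_sta) + val(i_stc)))
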