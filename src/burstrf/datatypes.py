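"""Core containers shared across the analysis stages.

All luminance values are expressed as mean-zero *contrast* (fraction of the
mean luminance), so a Gaussian-noise movie with 33% RMS contrast has pixel
standard deviation 0.33.  Spike times are seconds from stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusMovie", "SpikeRecord", "SubunitFilter", "OnOffMaps"]


@dataclass
class StimulusMovie:
    """A noise-movie stimulus: ``frames`` is (n_frames, rows, cols).

    Parameters
    ----------
    frames
        Luminance array in contrast units (mean zero).
    frame_duration
        Duration of one frame, seconds.
    kind
        ``"gaussian"`` (dense spatiotemporal white noise) or ``"sparse"``
        (one bright or dark square flashed per frame).
    rms_contrast
        Nominal RMS contrast of the generating distribution (gaussian) or
        flash amplitude (sparse).
    pixel_size_deg
        Side of one stimulus square in degrees of visual angle.
    seed
        Seed the movie was generated with (-1 for externally supplied data).
    """

    frames: np.ndarray
    frame_duration: float
    kind: str = "gaussian"
    rms_contrast: float = 0.33
    pixel_size_deg: float = 1.0
    seed: int = -1

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n_frames, rows, cols)")
        if self.frames.shape[0] < 1:
            raise ValueError("stimulus needs at least one frame")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")
        if self.kind not in ("gaussian", "sparse"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Total stimulus duration in seconds."""
        return self.n_frames * self.frame_duration


@dataclass
class SpikeRecord:
    """Spike times for one cell, possibly over repeats of a frozen stimulus.

    ``repeats`` is a list of strictly-ascending spike-time arrays (seconds).
    ``labels`` optionally carries per-spike integer codes (see
    :mod:`burstrf.bursts` for the classification codes); ``meta`` holds
    generator-side ground truth such as inserted burst times.
    """

    repeats: list[np.ndarray]
    stimulus_id: str = ""
    labels: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.repeats = [np.asarray(r, dtype=np.float64) for r in self.repeats]
        for r in self.repeats:
            if r.ndim != 1:
                raise ValueError("each repeat must be a 1-D time array")
            if r.size > 1 and np.any(np.diff(r) <= 0):
                raise ValueError("spike times must be strictly ascending")

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_spikes(self) -> int:
        return int(sum(r.size for r in self.repeats))


@dataclass
class SubunitFilter:
    """A spatiotemporal receptive-field subunit, (lags, rows, cols).

    ``kind`` is one of ``STA``, ``STC_k``, ``STA_ON``, ``STA_OFF`` or
    ``model``.  For STC subunits, ``weights`` is the unit-norm eigenvector
    reshaped to the stimulus window and ``eigenvalue``/``significant``/
    ``rank`` carry the covariance-analysis metadata.
    """

    weights: np.ndarray
    kind: str = "STA"
    eigenvalue: float | None = None
    significant: bool | None = None
    rank: int | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 3:
            raise ValueError("filter weights must be (lags, rows, cols)")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("filter weights must be finite")

    @property
    def n_lags(self) -> int:
        return self.weights.shape[0]

    @property
    def flat(self) -> np.ndarray:
        return self.weights.ravel()

    def peak_lag(self) -> int:
        """Lag index whose spatial map has the largest absolute value."""
        return int(np.argmax(np.max(np.abs(self.weights), axis=(1, 2))))

    def spatial_map(self, lag: int | None = None) -> np.ndarray:
        """Spatial (rows, cols) map at ``lag`` (default: the peak lag)."""
        if lag is None:
            lag = self.peak_lag()
        return self.weights[lag]


@dataclass
class OnOffMaps:
    """Separate bright/dark receptive-field maps from sparse noise."""

    sta_on: SubunitFilter
    sta_off: SubunitFilter
    overlap_percent: float
    peak_lag: int = 0
    on_defined: bool = True
    off_defined: bool = True
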