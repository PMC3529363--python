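"""Spatial structure of receptive-field subunits and ON/OFF reconstructions.

The *peak dominance ratio* compares the absolute maxima of the On and Off
subregions of a subunit's spatial map (stronger peak over weaker peak):
values near 1 mark balanced double-peaked maps, values above 2 maps
dominated by a single contrast.

The reconstruction operations test whether subunits recovered from dense
Gaussian noise can be explained by the separate ON/OFF maps recovered with
sparse noise: the first-order subunit as a weighted *sum*
(a * STA_ON + b * STA_OFF) and the second-order subunit as a weighted
pixel-wise *product* (c * STA_ON * STA_OFF).  Coefficients are optimised by
Nelder-Mead simplex descent on the sum of squared differences, compared at
the peak-amplitude lag; goodness of fit is a log signal-to-noise ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from burstrf.datatypes import SubunitFilter

logger = logging.getLogger(__name__)

__all__ = [
    "PeakDominance", "SubunitReconstruction",
    "peak_dominance", "reconstruct_sta", "reconstruct_stc", "snr",
]

SNR_CAP = 16.0  # log10 cap reported when the residual is exactly zero


@dataclass
class PeakDominance:
    ratio: float
    classification: str       # "single_peaked" | "double_peaked"
    dominant_sign: str        # "on" | "off" | "indeterminate"
    flagged: bool = False     # map lacked a genuine opposite-sign peak


@dataclass
class SubunitReconstruction:
    coefficients: tuple
    model_map: np.ndarray
    residual: np.ndarray
    snr: float
    flagged: bool = False


def _as_map(x, lag=None) -> np.ndarray:
    if isinstance(x, SubunitFilter):
        return x.spatial_map(lag)
    m = np.asarray(x, dtype=np.float64)
    if m.ndim == 3:
        peak = int(np.argmax(np.max(np.abs(m), axis=(1, 2))))
        return m[peak if lag is None else lag]
    if m.ndim != 2:
        raise ValueError("expected a 2-D spatial map")
    return m


def peak_dominance(subunit_map, dominance_threshold: float = 2.0,
                   sign_known: bool = True) -> PeakDominance:
    """Ratio of the stronger to the weaker opposite-sign peak of a map.

    ``sign_known=False`` (appropriate for STC subunits, whose overall sign
    is arbitrary) reports ``dominant_sign="indeterminate"``.
    """
    m = _as_map(subunit_map)
    if not np.any(m):
        raise ValueError("all-zero map")
    pos = float(m.max())
    neg = float(-m.min())
    flagged = pos <= 0 or neg <= 0
    if flagged:
        logger.warning("map is single-signed; the weaker 'peak' is noise-level")
    stronger = max(abs(pos), abs(neg))
    weaker = min(abs(pos), abs(neg))
    ratio = np.inf if weaker == 0 else stronger / weaker
    classification = "single_peaked" if ratio > dominance_threshold else "double_peaked"
    if not sign_known or pos == neg:
        dominant = "indeterminate"
    else:
        dominant = "on" if pos > neg else "off"
    return PeakDominance(ratio=float(ratio), classification=classification,
                         dominant_sign=dominant, flagged=flagged)


def snr(real_map, model_map, cap: float = SNR_CAP, base: float = 10.0) -> float:
    """log(power in the real map / residual power), base 10 by default."""
    real = np.asarray(real_map, dtype=np.float64)
    model = np.asarray(model_map, dtype=np.float64)
    if real.shape != model.shape:
        raise ValueError("maps must share a shape")
    p_real = float(np.sum(real ** 2))
    p_res = float(np.sum((real - model) ** 2))
    if p_res == 0:
        return cap
    return float(np.log(p_real / p_res) / np.log(base))


def _simplex_sse(target: np.ndarray, components: list[np.ndarray],
                 x0: np.ndarray) -> np.ndarray:
    def sse(coef):
        model = sum(c * comp for c, comp in zip(coef, components))
        return float(np.sum((target - model) ** 2))

    res = minimize(sse, x0, method="Nelder-Mead",
                   options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000})
    return res.x


def lstsq_coefficients(target: np.ndarray,
                       components: list[np.ndarray]) -> np.ndarray:
    """Closed-form least-squares coefficients (the STA model is linear in
    them); used as the independent check on the simplex optimiser."""
    A = np.stack([c.ravel() for c in components], axis=1)
    coef, *_ = np.linalg.lstsq(A, target.ravel(), rcond=None)
    return coef


def reconstruct_sta(sta_on, sta_off, target_sta,
                    method: str = "simplex") -> SubunitReconstruction:
    """Fit ``target = a * STA_ON + b * STA_OFF`` at the peak-amplitude lag.

    Separate coefficients for the bright and dark maps; ``method`` is
    ``"simplex"`` (Nelder-Mead on the SSE) or ``"lstsq"`` (closed form).
    """
    on = _as_map(sta_on)
    off = _as_map(sta_off)
    target = _as_map(target_sta)
    if not (on.shape == off.shape == target.shape):
        raise ValueError("maps must share a shape")
    if not np.any(on) and not np.any(off):
        raise ValueError("both ON and OFF maps are zero")
    x0 = lstsq_coefficients(target, [on, off])
    coef = x0 if method == "lstsq" else _simplex_sse(target, [on, off],
                                                     np.zeros(2))
    model = coef[0] * on + coef[1] * off
    residual = target - model
    return SubunitReconstruction(coefficients=(float(coef[0]), float(coef[1])),
                                 model_map=model, residual=residual,
                                 snr=snr(target, model))


def reconstruct_stc(sta_on, sta_off, target_stc,
                    method: str = "simplex") -> SubunitReconstruction:
    """Fit ``target = c * (STA_ON * STA_OFF)`` (pixel-wise product) at the
    peak-amplitude lag."""
    on = _as_map(sta_on)
    off = _as_map(sta_off)
    target = _as_map(target_stc)
    if not (on.shape == off.shape == target.shape):
        raise ValueError("maps must share a shape")
    product = on * off
    if not np.any(product):
        logger.warning("disjoint ON/OFF supports: product map is zero, "
                       "reconstruction undefined")
        return SubunitReconstruction(coefficients=(np.nan,),
                                     model_map=np.zeros_like(target),
                                     residual=target.copy(),
                                     snr=0.0, flagged=True)
    if method == "lstsq":
        coef = lstsq_coefficients(target, [product])
    else:
        coef = _simplex_sse(target, [product], np.zeros(1))
    model = coef[0] * product
    residual = target - model
    return SubunitReconstruction(coefficients=(float(coef[0]),),
                                 model_map=model, residual=residual,
                                 snr=snr(target, model))
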