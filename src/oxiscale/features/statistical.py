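"""Time-domain statistical descriptors of a saturation trace.

All functions operate on the valid samples of a series concatenated in time
order and return ``nan`` when the series is too short or degenerate, never
raising — so a short coarse-grained series degrades per feature.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def mean_abs_change(x: np.ndarray) -> float:
    """Average magnitude of change between consecutive samples."""
    if x.size < 2:
        return float("nan")
    return float(np.mean(np.abs(np.diff(x))))


def variance(x: np.ndarray) -> float:
    if x.size < 2:
        return float("nan")
    return float(np.var(x))


def kurtosis(x: np.ndarray) -> float:
    """Pearson (non-excess) kurtosis; 3 for a normal distribution."""
    if x.size < 4:
        return float("nan")
    if np.ptp(x) == 0:
        return float("nan")
    return float(stats.kurtosis(x, fisher=False, bias=True))


def zero_crossing_rate(x: np.ndarray) -> float:
    """Mean-crossing rate: sign changes of (x - mean) per transition.

    For saturation traces (never below 60 %) this is a *mean*-crossing count;
    samples exactly at the mean contribute no crossing.
    """
    if x.size < 2:
        return float("nan")
    s = np.sign(x - x.mean())
    return float(np.sum(s[:-1] * s[1:] < 0) / (x.size - 1))


def hjorth_mobility(x: np.ndarray) -> float:
    """sqrt(var(dx)/var(x)): normalised spectral spread of the signal."""
    if x.size < 3:
        return float("nan")
    vx = np.var(x)
    if vx == 0:
        return 0.0
    return float(np.sqrt(np.var(np.diff(x)) / vx))


def hjorth_complexity(x: np.ndarray) -> float:
    """mobility(dx)/mobility(x); nan when the series is constant (0/0)."""
    if x.size < 4:
        return float("nan")
    mob = hjorth_mobility(x)
    if not mob or np.isnan(mob):
        return float("nan")
    return float(hjorth_mobility(np.diff(x)) / mob)


def central_tendency_measure(x: np.ndarray, radius: float = 0.25) -> float:
    """Fraction of second-order-difference points inside a radius-`radius` disc.

    Points are (dx_i, dx_{i+1}) with dx the first difference; a signal whose
    consecutive changes are small (stable saturation) scores near 1.
    """
    if x.size < 4:
        return float("nan")
    d = np.diff(x)
    norms = np.hypot(d[:-1], d[1:])
    return float(np.mean(norms < radius))
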