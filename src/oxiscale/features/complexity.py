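"""Complexity and long-range-correlation measures: LZ76, DFA, PRSA capacity."""

from __future__ import annotations

import math

import numpy as np


def lz76_phrase_count(symbols: np.ndarray) -> int:
    """Number of distinct phrases in the Lempel-Ziv 1976 exhaustive parsing.

    Kaspar-Schuster scanning algorithm over an arbitrary symbol alphabet.
    """
    s = np.asarray(symbols)
    n = s.size
    if n == 0:
        return 0
    c, u, v, vmax = 1, 1, 1, 1
    i = 0
    while u + v <= n:
        if s[i + v - 1] == s[u + v - 1]:
            v += 1
        else:
            vmax = max(v, vmax)
            i += 1
            if i == u:  # no prefix reproduces the phrase: new phrase
                c += 1
                u += vmax
                v, i, vmax = 1, 0, 1
            else:
                v = 1
    if v != 1:
        c += 1
    return c


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalised LZ76 complexity of the median-binarised signal.

    The signal is binarised at its median (ties to the "below" symbol) and
    the phrase count is normalised by the random-sequence growth rate
    n / log2(n), giving ~1 for white noise and ~0 for regular signals.
    """
    if x.size < 4:
        return float("nan")
    b = (x > np.median(x)).astype(np.int8)
    c = lz76_phrase_count(b)
    n = x.size
    return float(c / (n / math.log2(n)))


def _dfa_fluctuations(
    profile: np.ndarray, window_sizes: np.ndarray, overlap: bool
) -> np.ndarray:
    f = np.empty(window_sizes.size)
    n = profile.size
    t = np.arange(n, dtype=float)
    for k, w in enumerate(window_sizes):
        step = max(1, w // 2) if overlap else w
        starts = range(0, n - w + 1, step)
        sq = 0.0
        cnt = 0
        for s in starts:
            seg = profile[s : s + w]
            tt = t[s : s + w]
            coef = np.polyfit(tt, seg, 1)
            resid = seg - np.polyval(coef, tt)
            sq += float((resid**2).mean())
            cnt += 1
        f[k] = math.sqrt(sq / cnt)
    return f


def dfa_alpha(
    x: np.ndarray,
    win_min: int = 4,
    win_max: int | None = None,
    n_windows: int = 12,
    overlap: bool = False,
) -> float:
    """Detrended-fluctuation-analysis scaling exponent.

    The profile (cumulative sum of the mean-subtracted signal) is split into
    windows of w samples, linearly detrended per window, and the RMS residual
    F(w) is fitted against w on log-log axes; the slope is alpha (0.5 for
    uncorrelated noise, 1.0 for 1/f noise).  Non-overlapping windows by
    default; ``overlap=True`` steps by w/2.  Returns nan when fewer than two
    feasible window sizes exist.
    """
    n = x.size
    if win_max is None:
        win_max = n // 4
    if n < 4 * win_min or win_max <= win_min:
        return float("nan")
    sizes = np.unique(
        np.round(np.exp(np.linspace(math.log(win_min), math.log(win_max), n_windows)))
    ).astype(int)
    sizes = sizes[(sizes >= win_min) & (sizes <= win_max)]
    if sizes.size < 2:
        return float("nan")
    profile = np.cumsum(x - x.mean())
    f = _dfa_fluctuations(profile, sizes, overlap)
    good = f > 0
    if good.sum() < 2:
        return float("nan")
    slope = np.polyfit(np.log(sizes[good]), np.log(f[good]), 1)[0]
    return float(slope)


def prsa_capacity(x: np.ndarray, d: int = 10) -> float:
    """Phase-rectified signal averaging capacity with fragment half-length d.

    Anchors are samples that decrease relative to their predecessor; windows
    x[i-d .. i+d-1] around each interior anchor are averaged into the PRSA
    curve xbar(-d..d-1), and the capacity is the Haar-wavelet amplitude
    (xbar(0) + xbar(1) - xbar(-1) - xbar(-2)) / 4.  Returns nan when the
    series is too short or has no interior anchors (e.g. monotone
    non-decreasing signals).
    """
    n = x.size
    if d < 2 or n < 2 * d + 2:
        return float("nan")
    idx = np.arange(1, n)
    anchors = idx[x[1:] < x[:-1]]
    anchors = anchors[(anchors >= d) & (anchors <= n - d)]
    if anchors.size == 0:
        return float("nan")
    offsets = np.arange(-d, d)
    windows = x[anchors[:, None] + offsets[None, :]]
    xbar = windows.mean(axis=0)  # index k -> offset k - d
    return float((xbar[d] + xbar[d + 1] - xbar[d - 1] - xbar[d - 2]) / 4.0)
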