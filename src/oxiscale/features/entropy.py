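"""Entropy measures of saturation dynamics.

Each estimator is a pure function of a 1-D array of valid samples.  The
tolerance-based family (ApEn, SampEn, FuzzEn, K2En) measures template
regularity relative to a tolerance ``r`` expressed as a fraction of the
series' standard deviation; symbolic estimators (PermEn, DispEn, IncrEn,
CondEn, ShannonEn, PhasEn, ComplexEn) discretise the signal first.

Conventions for degenerate input: a constant series (sd = 0) has zero
irregularity, so the tolerance- and symbol-based entropies return 0.0 (the
tolerance r = 0.25*sd would otherwise be ill-defined); series too short for a
given embedding return ``nan``.

Pairwise template scans run in row blocks with component-wise 2-D
arithmetic, keeping memory at O(block * n) while covering all O(n^2) pairs.
"""

from __future__ import annotations

import logging
import math

import numpy as np
from scipy import special

logger = logging.getLogger(__name__)

_CHUNK = 1024  # row block for pairwise scans


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    """(n - (m-1)*delay) x m matrix of delay vectors."""
    n = x.size - (m - 1) * delay
    if n <= 0:
        return np.empty((0, m))
    idx = np.arange(n)[:, None] + np.arange(m)[None, :] * delay
    return x[idx]


def _cheb_block(block: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Chebyshev distances between every row of `block` and of `t` (2-D ops)."""
    d = np.abs(block[:, 0][:, None] - t[:, 0][None, :])
    for k in range(1, t.shape[1]):
        np.maximum(d, np.abs(block[:, k][:, None] - t[:, k][None, :]), out=d)
    return d


def _cheb_match_count(t: np.ndarray, r: float, exclude_self: bool) -> int:
    """Ordered template pairs with Chebyshev distance <= r."""
    n = t.shape[0]
    total = 0
    for lo in range(0, n, _CHUNK):
        block = t[lo : lo + _CHUNK]
        within = np.abs(block[:, 0][:, None] - t[:, 0][None, :]) <= r
        for k in range(1, t.shape[1]):
            within &= np.abs(block[:, k][:, None] - t[:, k][None, :]) <= r
        total += int(within.sum())
        if exclude_self:
            total -= block.shape[0]
    return total


def approximate_entropy(x: np.ndarray, m: int = 1, r_frac: float = 0.25) -> float:
    """ApEn: phi(m) - phi(m+1) with self-matches included (Pincus)."""
    if x.size < m + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        n = t.shape[0]
        logs = 0.0
        for lo in range(0, n, _CHUNK):
            block = t[lo : lo + _CHUNK]
            within = np.abs(block[:, 0][:, None] - t[:, 0][None, :]) <= r
            for k in range(1, mm):
                within &= np.abs(block[:, k][:, None] - t[:, k][None, :]) <= r
            counts = within.sum(axis=1)  # self-match included
            logs += float(np.log(counts / n).sum())
        return logs / n

    return phi(m) - phi(m + 1)


def sample_entropy(x: np.ndarray, m: int = 1, r_frac: float = 0.25) -> float:
    """SampEn: -ln(A/B) over template matches at m+1 (A) and m (B), no self-matches.

    Templates at length m are truncated to n-m so A and B count the same
    index set (Richman & Moorman).
    """
    if x.size < m + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd
    tm = _embed(x, m)[: x.size - m]
    tm1 = _embed(x, m + 1)
    b = _cheb_match_count(tm, r, exclude_self=True)
    a = _cheb_match_count(tm1, r, exclude_self=True)
    if b == 0 or a == 0:
        return float("nan")
    return float(-math.log(a / b))


def fuzzy_entropy(
    x: np.ndarray, m: int = 2, r_frac: float = 0.25, exponent: float = 2.0
) -> float:
    """FuzzEn with mean-subtracted templates and membership exp(-(d/r)^p)."""
    if x.size < m + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        t = t - t.mean(axis=1, keepdims=True)
        n = t.shape[0]
        s = 0.0
        for lo in range(0, n, _CHUNK):
            block = t[lo : lo + _CHUNK]
            d = _cheb_block(block, t)
            d /= r
            if exponent == 2.0:
                np.multiply(d, d, out=d)
            else:
                np.power(d, exponent, out=d)
            np.negative(d, out=d)
            np.exp(d, out=d)
            s += float(d.sum()) - block.shape[0]  # drop self-pairs (mu=1)
        return s / (n * (n - 1))

    p_m, p_m1 = phi(m), phi(m + 1)
    if p_m <= 0 or p_m1 <= 0:
        return float("nan")
    return float(math.log(p_m) - math.log(p_m1))


def k2_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.25) -> float:
    """Kolmogorov (K2) entropy estimate ln(C_m / C_{m+1}) from correlation sums.

    Correlation sums use Euclidean distances between delay vectors, no
    self-matches (Grassberger & Procaccia).
    """
    if x.size < m + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def corr_sum(mm: int) -> float:
        t = _embed(x, mm)
        n = t.shape[0]
        cnt = 0
        for lo in range(0, n, _CHUNK):
            block = t[lo : lo + _CHUNK]
            d2 = (block[:, 0][:, None] - t[:, 0][None, :]) ** 2
            for k in range(1, mm):
                d2 += (block[:, k][:, None] - t[:, k][None, :]) ** 2
            cnt += int((d2 <= r * r).sum()) - block.shape[0]
        return cnt / (n * (n - 1))

    c_m, c_m1 = corr_sum(m), corr_sum(m + 1)
    if c_m <= 0 or c_m1 <= 0:
        return float("nan")
    return float(math.log(c_m / c_m1))


def _ordinal_distribution(x: np.ndarray, order: int, delay: int) -> np.ndarray:
    """Relative frequencies of ordinal patterns (ties broken by position)."""
    t = _embed(x, order, delay)
    if t.shape[0] == 0:
        return np.empty(0)
    patterns = np.argsort(t, axis=1, kind="stable")
    weights = (order ** np.arange(order)).astype(np.int64)
    codes = patterns @ weights
    _, counts = np.unique(codes, return_counts=True)
    return counts / counts.sum()


def permutation_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """PermEn of ordinal patterns, normalised to [0, 1] by ln(order!)."""
    if x.size < (order - 1) * delay + 2:
        return float("nan")
    p = _ordinal_distribution(x, order, delay)
    if p.size == 0:
        return float("nan")
    h = float(-(p * np.log(p)).sum())
    return h / math.log(math.factorial(order))


def complexity_entropy(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Ordinal statistical complexity C = H_norm * Q_JS in [0, 1].

    H_norm is the normalised permutation entropy and Q_JS the Jensen-Shannon
    disequilibrium between the ordinal distribution and the uniform one,
    normalised by its maximum (Martin-Plastino-Rosso complexity).  Both a
    constant and a fully random signal score 0.
    """
    if x.size < (order - 1) * delay + 2:
        return float("nan")
    p_obs = _ordinal_distribution(x, order, delay)
    if p_obs.size == 0:
        return float("nan")
    n_pat = math.factorial(order)
    p = np.zeros(n_pat)
    p[: p_obs.size] = np.sort(p_obs)[::-1]  # JS terms depend only on the multiset
    u = np.full(n_pat, 1.0 / n_pat)

    def shannon(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    h_norm = shannon(p) / math.log(n_pat)
    js = shannon(0.5 * (p + u)) - 0.5 * shannon(p) - 0.5 * shannon(u)
    # maximum JS disequilibrium: a certain pattern vs the uniform distribution
    q0 = ((n_pat + 1) / n_pat) * math.log(n_pat + 1) - 2 * math.log(2 * n_pat) + math.log(n_pat)
    js_max = -0.5 * q0
    return float(h_norm * js / js_max)


def shannon_entropy(x: np.ndarray, bin_edges: np.ndarray | None = None) -> float:
    """Histogram (Shannon) entropy in nats over the saturation range.

    Default bins are the 41 one-percent bins centred on 60..100 %.
    """
    if x.size < 2:
        return float("nan")
    if bin_edges is None:
        bin_edges = np.arange(59.5, 101.0, 1.0)
    counts, _ = np.histogram(x, bins=bin_edges)
    total = counts.sum()
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def dispersion_entropy(
    x: np.ndarray, classes: int = 6, m: int = 2, delay: int = 1
) -> float:
    """DispEn via normal-CDF mapping into `classes` levels, normalised by ln(c^m)."""
    if x.size < (m - 1) * delay + 2:
        return float("nan")
    sd = x.std()
    if sd == 0:
        return 0.0
    y = special.ndtr((x - x.mean()) / sd)
    z = np.clip(np.round(classes * y + 0.5), 1, classes).astype(np.int64)
    t = _embed(z.astype(float), m, delay).astype(np.int64)
    codes = (t * (classes ** np.arange(m))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / (m * math.log(classes))


def increment_entropy(x: np.ndarray, quant: int = 4, m: int = 2) -> float:
    """IncrEn: entropy (base 2) of words of m sign/magnitude-coded increments.

    Each increment is coded by its sign and its magnitude quantised to
    0..quant in units of the increment standard deviation; word entropy is
    divided by (m - 1) following the original definition.
    """
    if x.size < m + 2:
        return float("nan")
    d = np.diff(x)
    sd = d.std()
    if sd == 0:
        return 0.0
    s = np.sign(d).astype(np.int64)
    q = np.minimum(quant, np.floor(np.abs(d) * quant / sd)).astype(np.int64)
    sym = s * (q + 1) + quant + 1  # unique non-negative code per (sign, magnitude)
    base = 2 * quant + 3
    t = _embed(sym.astype(float), m).astype(np.int64)
    codes = (t * (base ** np.arange(m))).sum(axis=1)
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    h = float(-(p * np.log2(p)).sum())
    return h / (m - 1) if m > 1 else h


def conditional_entropy(
    x: np.ndarray, classes: int = 6, max_order: int = 5
) -> float:
    """Corrected conditional entropy (Porta): min over word length m of
    E(m) - E(m-1) + perc(m) * E(1), with uniform amplitude quantisation.

    perc(m) is the fraction of length-m words occurring exactly once; the
    correction charges unresolvable (singleton) patterns with the first-order
    entropy, so the minimum over m is a consistent complexity index.
    """
    if x.size < max_order + 2:
        return float("nan")
    rng = np.ptp(x)
    if rng == 0:
        return 0.0
    z = np.minimum((classes * (x - x.min()) / rng).astype(np.int64), classes - 1)

    def word_stats(mm: int) -> tuple[float, float]:
        t = _embed(z.astype(float), mm).astype(np.int64)
        codes = (t * (classes ** np.arange(mm))).sum(axis=1)
        _, counts = np.unique(codes, return_counts=True)
        p = counts / counts.sum()
        h = float(-(p * np.log(p)).sum())
        perc = float((counts == 1).sum() / counts.sum())
        return h, perc

    e1, _ = word_stats(1)
    best = e1
    prev = e1
    for mm in range(2, max_order + 1):
        e_m, perc = word_stats(mm)
        cce = e_m - prev + perc * e1
        best = min(best, cce)
        prev = e_m
    return best


def distribution_entropy(x: np.ndarray, m: int = 2, bins: int = 512) -> float:
    """DistEn: histogram entropy (base 2) of inter-template Chebyshev distances,
    normalised by log2(bins) (Li et al.)."""
    if x.size < m + 2:
        return float("nan")
    t = _embed(x, m)
    n = t.shape[0]
    # two passes over the strict upper triangle: maximum, then histogram
    vmax = 0.0
    for i in range(0, n, _CHUNK):
        block = t[i : i + _CHUNK]
        vmax = max(vmax, float(_cheb_block(block, t[i:]).max()))
    if vmax == 0.0:
        return 0.0
    counts = np.zeros(bins, dtype=np.int64)
    total = 0
    for i in range(0, n, _CHUNK):
        block = t[i : i + _CHUNK]
        d = _cheb_block(block, t[i:])
        rows = np.arange(block.shape[0])[:, None]
        cols = np.arange(d.shape[1])[None, :]
        vals = d[cols > rows]
        c, _ = np.histogram(vals, bins=bins, range=(0.0, vmax))
        counts += c
        total += vals.size
    if total == 0:
        return float("nan")
    p = counts[counts > 0] / total
    h = float(-(p * np.log2(p)).sum())
    return h / math.log2(bins)


def phase_entropy(x: np.ndarray, sectors: int = 8) -> float:
    """PhasEn: entropy of the angle distribution of the second-order
    difference plot (dx_i, dx_{i+1}), in `sectors` equal sectors, normalised."""
    if x.size < 4:
        return float("nan")
    d = np.diff(x)
    u, v = d[:-1], d[1:]
    keep = (u != 0) | (v != 0)
    if not keep.any():
        return 0.0
    theta = np.arctan2(v[keep], u[keep])  # (-pi, pi]
    idx = np.minimum(((theta + np.pi) / (2 * np.pi) * sectors).astype(int), sectors - 1)
    counts = np.bincount(idx, minlength=sectors)
    p = counts[counts > 0] / counts.sum()
    h = float(-(p * np.log(p)).sum())
    return h / math.log(sectors)
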