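"""Brute-force reference implementations used as independent oracles.

Everything here is written with explicit Python loops over template pairs,
mirroring the estimators' definitions directly; no code is shared with the
package's vectorised implementations.
"""

import math
from collections import Counter

from scipy.special import ndtr


def cheb(a, b):
    return max(abs(x - y) for x, y in zip(a, b))


def templates(x, m, delay=1):
    n = len(x) - (m - 1) * delay
    return [tuple(x[i + k * delay] for k in range(m)) for i in range(n)]


def apen(x, m, r_frac):
    sd = _std(x)
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm):
        ts = templates(x, mm)
        n = len(ts)
        total = 0.0
        for a in ts:
            c = sum(1 for b in ts if cheb(a, b) <= r)
            total += math.log(c / n)
        return total / n

    return phi(m) - phi(m + 1)


def sampen(x, m, r_frac):
    sd = _std(x)
    if sd == 0:
        return 0.0
    r = r_frac * sd
    tm = templates(x, m)[: len(x) - m]
    tm1 = templates(x, m + 1)

    def count(ts):
        c = 0
        for i, a in enumerate(ts):
            for j, b in enumerate(ts):
                if i != j and cheb(a, b) <= r:
                    c += 1
        return c

    b, a = count(tm), count(tm1)
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def fuzzen(x, m, r_frac, p=2.0):
    sd = _std(x)
    if sd == 0:
        return 0.0
    r = r_frac * sd

    def phi(mm):
        ts = []
        for t in templates(x, mm):
            mu = sum(t) / mm
            ts.append(tuple(v - mu for v in t))
        n = len(ts)
        s = 0.0
        for i, a in enumerate(ts):
            for j, b in enumerate(ts):
                if i != j:
                    s += math.exp(-((cheb(a, b) / r) ** p))
        return s / (n * (n - 1))

    return math.log(phi(m)) - math.log(phi(m + 1))


def permen(x, order, delay=1):
    counts = Counter()
    for t in templates(x, order, delay):
        pattern = tuple(sorted(range(order), key=lambda k: (t[k], k)))
        counts[pattern] += 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(order))


def dispen(x, classes, m):
    sd = _std(x)
    if sd == 0:
        return 0.0
    mean = sum(x) / len(x)
    z = []
    for v in x:
        y = float(ndtr((v - mean) / sd))
        z.append(min(classes, max(1, round(classes * y + 0.5))))
    counts = Counter(tuple(z[i:i + m]) for i in range(len(z) - m + 1))
    total = sum(counts.values())
    h = -sum((c / total) * math.log(c / total) for c in counts.values())
    return h / (m * math.log(classes))


def incren(x, quant, m):
    d = [b - a for a, b in zip(x, x[1:])]
    sd = _std(d, ddof=0)
    if sd == 0:
        return 0.0
    sym = []
    for v in d:
        s = 0 if v == 0 else (1 if v > 0 else -1)
        q = min(quant, math.floor(abs(v) * quant / sd))
        sym.append((s, q))
    counts = Counter(tuple(sym[i:i + m]) for i in range(len(sym) - m + 1))
    total = sum(counts.values())
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return h / (m - 1) if m > 1 else h


def conden(x, classes, max_order):
    lo, hi = min(x), max(x)
    if hi == lo:
        return 0.0
    z = [min(int(classes * (v - lo) / (hi - lo)), classes - 1) for v in x]

    def stats(mm):
        counts = Counter(tuple(z[i:i + mm]) for i in range(len(z) - mm + 1))
        total = sum(counts.values())
        h = -sum((c / total) * math.log(c / total) for c in counts.values())
        perc = sum(1 for c in counts.values() if c == 1) / total
        return h, perc

    e1, _ = stats(1)
    best, prev = e1, e1
    for mm in range(2, max_order + 1):
        e_m, perc = stats(mm)
        best = min(best, e_m - prev + perc * e1)
        prev = e_m
    return best


def disten(x, m, bins):
    import bisect

    import numpy as np

    ts = templates(x, m)
    dists = []
    for i in range(len(ts)):
        for j in range(i + 1, len(ts)):
            dists.append(cheb(ts[i], ts[j]))
    vmax = max(dists)
    if vmax == 0:
        return 0.0
    # same bin edges as numpy.histogram so edge assignment is identical;
    # the entropy computation below stays loop-based and independent
    edges = np.histogram_bin_edges(dists, bins=bins, range=(0.0, vmax))
    counts = [0] * bins
    for d in dists:
        k = min(bins - 1, bisect.bisect_right(list(edges), d) - 1)
        counts[k] += 1
    total = len(dists)
    h = -sum((c / total) * math.log2(c / total) for c in counts if c)
    return h / math.log2(bins)


def spearman_rho(x, y):
    """Textbook Spearman: Pearson correlation of average ranks."""
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    n = len(x)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def mcc_binary(tp, fn, fp, tn):
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return (tp * tn - fp * fn) / den if den else 0.0


def _std(x, ddof=0):
    n = len(x)
    mean = sum(x) / n
    return math.sqrt(sum((v - mean) ** 2 for v in x) / (n - ddof))
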