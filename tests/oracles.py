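"""Naive reference implementations of the entropy estimators.

Deliberately slow, loop-based, written directly from the defining formulas,
and independent of the package's vectorized/compiled code paths.  Used only
to cross-check the production estimators.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def sampen_naive(x, m=2, r_coeff=0.15):
    x = np.asarray(x, dtype=float)
    r = r_coeff * float(np.std(x))
    nt = x.size - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m <= r:
                b += 1
                d_m1 = max(d_m, abs(x[i + m] - x[j + m]))
                if d_m1 <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def fuzzen_naive(x, m=2, r=0.0077, n=3.0, variant="local"):
    x = np.asarray(x, dtype=float)
    if variant == "global":
        x = x - x.mean()

    def phi(order):
        nt = x.size - m  # same template count at both orders
        vecs = []
        for i in range(nt):
            v = x[i:i + order].copy()
            if variant == "local":
                v = v - v.mean()
            vecs.append(v)
        total = 0.0
        count = 0
        for i in range(nt - 1):
            for j in range(i + 1, nt):
                d = max(abs(vecs[i][k] - vecs[j][k]) for k in range(order))
                total += math.exp(-((d / r) ** n))
                count += 1
        return total / count

    return math.log(max(phi(m), 1e-300)) - math.log(max(phi(m + 1), 1e-300))


def peren_naive(x, order=3, delay=2, normalize=True):
    x = np.asarray(x, dtype=float)
    n_vec = x.size - (order - 1) * delay
    patterns = Counter()
    for i in range(n_vec):
        v = [x[i + k * delay] for k in range(order)]
        # rank vector with ties broken by order of appearance
        idx = sorted(range(order), key=lambda k: (v[k], k))
        patterns[tuple(idx)] += 1
    h = -sum((c / n_vec) * math.log(c / n_vec) for c in patterns.values())
    if normalize:
        h /= math.log(math.factorial(order))
    return h


def dispen_naive(x, m=2, c=3):
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 0.0
    classes = [min(int(c * (v - lo) / (hi - lo)) + 1, c) for v in x]
    n_vec = x.size - m + 1
    patterns = Counter(tuple(classes[i:i + m]) for i in range(n_vec))
    h = -sum((cnt / n_vec) * math.log(cnt / n_vec)
             for cnt in patterns.values())
    return h / math.log(c ** m)


def _bubble_swaps(v):
    """Swap count of an actual bubble sort."""
    v = list(v)
    swaps = 0
    for end in range(len(v) - 1, 0, -1):
        for i in range(end):
            if v[i] > v[i + 1]:
                v[i], v[i + 1] = v[i + 1], v[i]
                swaps += 1
    return swaps


def ben_naive(x, m=10):
    x = np.asarray(x, dtype=float)

    def renyi2(order):
        n_vec = x.size - order + 1
        counts = Counter(_bubble_swaps(x[i:i + order]) for i in range(n_vec))
        return -math.log(sum((c / n_vec) ** 2 for c in counts.values()))

    return (renyi2(m + 1) - renyi2(m)) / math.log((m + 1) / (m - 1))


def phen_naive(x, k):
    x = np.asarray(x, dtype=float)
    pts = [(x[i + 1] - x[i], x[i + 2] - x[i + 1])
           for i in range(x.size - 2)]
    pts = [(px, py) for px, py in pts if not (px == 0 and py == 0)]
    width = 2 * math.pi / k
    sectors = Counter()
    for px, py in pts:
        theta = math.atan2(py, px) % (2 * math.pi)
        sectors[min(int(theta // width), k - 1)] += 1
    total = len(pts)
    h = -sum((c / total) * math.log(c / total) for c in sectors.values())
    return h / math.log(k)
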