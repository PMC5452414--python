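"""Independent brute-force reference implementations used to cross-check
the package's fast code paths. Everything here works with exact rational
arithmetic or naive per-bp bitmaps and never imports the implementation
under test."""

from fractions import Fraction
from math import comb

import numpy as np


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact enumeration over all tables with the
    observed margins (point-probability rule, exact rational comparison)."""
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)
    obs = Fraction(comb(r1, a) * comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= obs:
            total += pk
    return float(total)


def binomial_oracle(x1: int, x2: int, n1: int, n2: int) -> float:
    """Two-sided conditional binomial p by exact enumeration."""
    x1, x2, n1, n2 = int(x1), int(x2), int(n1), int(n2)
    n = x1 + x2
    p = Fraction(n1, n1 + n2)
    q = 1 - p

    def pmf(k):
        return comb(n, k) * p**k * q ** (n - k)

    obs = pmf(x1)
    return float(sum(pmf(k) for k in range(n + 1) if pmf(k) <= obs))


def bh_oracle(pvals) -> np.ndarray:
    """BH step-up via the literal definition, O(n^2) loop."""
    p = list(pvals)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    for rank_pos in range(n):
        i = order[rank_pos]
        best = 1.0
        for later in range(rank_pos, n):
            j = order[later]
            best = min(best, p[j] * n / (later + 1))
        q[i] = min(1.0, best)
    return np.array(q)


def merge_bins_oracle(bins, join_gap):
    """Join sorted (start, end) bins with gap <= join_gap, naive loop."""
    if not bins:
        return []
    bins = sorted(bins)
    out = [list(bins[0])]
    for s, e in bins[1:]:
        if s - out[-1][1] <= join_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


class Bitmap:
    """Per-bp boolean bitmap for interval-algebra cross-checks."""

    def __init__(self, length, intervals=()):
        self.mask = np.zeros(length, dtype=bool)
        for s, e in intervals:
            self.mask[s:e] = True

    def intervals(self):
        out = []
        in_run = False
        for i, v in enumerate(self.mask):
            if v and not in_run:
                start, in_run = i, True
            elif not v and in_run:
                out.append((start, i))
                in_run = False
        if in_run:
            out.append((start, len(self.mask)))
        return out

    def total(self):
        return int(self.mask.sum())

    def __and__(self, other):
        r = Bitmap(len(self.mask))
        r.mask = self.mask & other.mask
        return r

    def __or__(self, other):
        r = Bitmap(len(self.mask))
        r.mask = self.mask | other.mask
        return r

    def __sub__(self, other):
        r = Bitmap(len(self.mask))
        r.mask = self.mask & ~other.mask
        return r

    def __invert__(self):
        r = Bitmap(len(self.mask))
        r.mask = ~self.mask
        return r


def random_intervals(rng, n, length, max_len=50):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, max(1, length - 1)))
        e = min(length, s + 1 + int(rng.integers(0, max_len)))
        out.append((s, e))
    return out
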