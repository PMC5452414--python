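"""Half-open interval primitives on per-chromosome coordinate arrays.

All functions take parallel ``starts``/``ends`` integer arrays describing
0-based half-open intervals on a single chromosome. Higher-level,
DataFrame-based operations live in :mod:`binmeth.regions`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "merge",
    "total_length",
    "coverage",
    "intersect",
    "subtract",
    "complement",
    "overlapping_pairs",
]


def _as_arrays(starts, ends):
    s = np.asarray(starts, dtype=np.int64)
    e = np.asarray(ends, dtype=np.int64)
    if s.shape != e.shape:
        raise ValueError("starts and ends must have the same shape")
    if np.any(e <= s):
        raise ValueError("intervals must satisfy start < end")
    return s, e


def merge(starts, ends, gap: int = 0):
    """Merge intervals whose gap (next start minus running end) is <= ``gap``.

    With ``gap=0`` touching or overlapping intervals coalesce. Returns
    sorted, disjoint ``(starts, ends)``.
    """
    s, e = _as_arrays(starts, ends)
    if s.size == 0:
        return s, e
    order = np.argsort(s, kind="stable")
    s, e = s[order], e[order]
    run_end = np.maximum.accumulate(e)
    new_grp = np.empty(s.size, dtype=bool)
    new_grp[0] = True
    new_grp[1:] = s[1:] > run_end[:-1] + gap
    first = np.nonzero(new_grp)[0]
    out_s = s[first]
    out_e = np.maximum.reduceat(e, first)
    return out_s, out_e


def total_length(starts, ends) -> int:
    """Total bp covered by the union of the intervals."""
    s, e = merge(starts, ends)
    return int(np.sum(e - s))


def coverage(q_starts, q_ends, m_starts, m_ends) -> np.ndarray:
    """Per-query overlap in bp with a *merged* (disjoint, sorted) set."""
    qs = np.asarray(q_starts, dtype=np.int64)
    qe = np.asarray(q_ends, dtype=np.int64)
    ms = np.asarray(m_starts, dtype=np.int64)
    me = np.asarray(m_ends, dtype=np.int64)
    if ms.size == 0:
        return np.zeros(qs.shape, dtype=np.int64)
    lengths = me - ms
    cum = np.concatenate([[0], np.cumsum(lengths)])

    def covered_upto(x):
        j = np.searchsorted(ms, x, side="right") - 1
        jj = np.maximum(j, 0)
        extra = np.clip(x - ms[jj], 0, lengths[jj])
        return np.where(j < 0, 0, cum[jj] + extra)

    return covered_upto(qe) - covered_upto(qs)


def intersect(a_starts, a_ends, b_starts, b_ends):
    """Intersection intervals of the unions of two interval sets."""
    a_s, a_e = merge(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    out_s, out_e = [], []
    i = j = 0
    while i < a_s.size and j < b_s.size:
        lo = max(a_s[i], b_s[j])
        hi = min(a_e[i], b_e[j])
        if lo < hi:
            out_s.append(lo)
            out_e.append(hi)
        if a_e[i] <= b_e[j]:
            i += 1
        else:
            j += 1
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def subtract(a_starts, a_ends, b_starts, b_ends):
    """Union of ``a`` minus union of ``b``."""
    a_s, a_e = merge(a_starts, a_ends)
    b_s, b_e = merge(b_starts, b_ends)
    out_s, out_e = [], []
    j = 0
    for s, e in zip(a_s, a_e):
        cur = s
        while j < b_s.size and b_e[j] <= cur:
            j += 1
        k = j
        while k < b_s.size and b_s[k] < e:
            if b_s[k] > cur:
                out_s.append(cur)
                out_e.append(min(b_s[k], e))
            cur = max(cur, b_e[k])
            if cur >= e:
                break
            k += 1
        if cur < e:
            out_s.append(cur)
            out_e.append(e)
    return np.array(out_s, dtype=np.int64), np.array(out_e, dtype=np.int64)


def complement(starts, ends, chrom_length: int):
    """Gaps of the union within ``[0, chrom_length)``."""
    return subtract(
        np.array([0], dtype=np.int64),
        np.array([chrom_length], dtype=np.int64),
        starts,
        ends,
    )


def overlapping_pairs(a_starts, a_ends, b_starts, b_ends, min_bp: int = 1):
    """Indices ``(ia, ib)`` of interval pairs overlapping by >= ``min_bp`` bp.

    Indices refer to the input order of each set (not merged).
    """
    a_s = np.asarray(a_starts, dtype=np.int64)
    a_e = np.asarray(a_ends, dtype=np.int64)
    b_s = np.asarray(b_starts, dtype=np.int64)
    b_e = np.asarray(b_ends, dtype=np.int64)
    ia_out, ib_out = [], []
    order_a = np.argsort(a_s, kind="stable")
    order_b = np.argsort(b_s, kind="stable")
    bs, be = b_s[order_b], b_e[order_b]
    j_lo = 0
    max_b_end = np.maximum.accumulate(be) if be.size else be
    for ia in order_a:
        s, e = a_s[ia], a_e[ia]
        # advance past b intervals that can never overlap again
        while j_lo < bs.size and max_b_end[j_lo] <= s:
            j_lo += 1
        for j in range(j_lo, bs.size):
            if bs[j] >= e:
                break
            ov = min(e, be[j]) - max(s, bs[j])
            if ov >= min_bp:
                ia_out.append(ia)
                ib_out.append(order_b[j])
    return np.array(ia_out, dtype=np.int64), np.array(ib_out, dtype=np.int64)
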