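"""Exact count tests and multiple-testing correction.

All differential callers in this package reduce to one of two exact
conditional tests on a pair of counts:

* :func:`fisher_exact_2x2` — two-sided Fisher's exact test on a 2x2 table
  of pooled methylated/unmethylated counts;
* :func:`conditional_binomial_test` — an exact rate comparison for two
  count libraries, conditioning on the total count.

Both use the "point probability" two-sided rule: the p-value is the sum of
the probabilities of all outcomes whose point probability does not exceed
that of the observed outcome (a small relative tolerance absorbs floating
point ties, as in other common implementations).

Vectorised variants (``*_many``) evaluate many tests in chunks and are the
code path the callers use; the scalar functions validate their inputs and
delegate to them.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

__all__ = [
    "fisher_exact_2x2",
    "fisher_exact_many",
    "conditional_binomial_test",
    "conditional_binomial_many",
    "bh_adjust",
]

# relative tolerance when comparing point probabilities (log scale)
_LOG_REL_TOL = np.log1p(1e-7)

_CHUNK = 4096


def _log_comb(n: np.ndarray, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _check_count(name: str, value) -> int:
    if isinstance(value, (bool, np.bool_)):
        raise ValueError(f"{name} must be a non-negative integer, got {value!r}")
    if isinstance(value, float) and not float(value).is_integer():
        raise ValueError(f"{name} must be an integer, got {value!r}")
    iv = int(value)
    if iv != value:
        raise ValueError(f"{name} must be an integer, got {value!r}")
    if iv < 0:
        raise ValueError(f"{name} must be non-negative, got {value!r}")
    return iv


def fisher_exact_2x2(a, b, c, d) -> float:
    """Two-sided Fisher's exact test for the 2x2 table ``[[a, b], [c, d]]``.

    Returns the sum over all tables with the observed margins whose
    hypergeometric point probability is at most that of the observed table.

    Raises
    ------
    ValueError
        If any count is negative or non-integer, or if all four counts are
        zero (the test is undefined).
    """
    a = _check_count("a", a)
    b = _check_count("b", b)
    c = _check_count("c", c)
    d = _check_count("d", d)
    if a + b + c + d == 0:
        raise ValueError("Fisher test undefined for the all-zero table")
    return float(
        fisher_exact_many(
            np.array([a]), np.array([b]), np.array([c]), np.array([d])
        )[0]
    )


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Vectorised two-sided Fisher's exact test.

    Parameters are equal-length arrays of non-negative integers; rows with
    an all-zero table yield NaN.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    r1 = a + b
    r2 = c + d
    c1 = a + c
    n = r1 + r2
    out = np.full(a.shape, np.nan)
    ok = n > 0
    idx = np.nonzero(ok)[0]
    for start in range(0, idx.size, _CHUNK):
        rows = idx[start : start + _CHUNK]
        out[rows] = _fisher_chunk(a[rows], r1[rows], r2[rows], c1[rows], n[rows])
    return out


def _fisher_chunk(a, r1, r2, c1, n) -> np.ndarray:
    lo = np.maximum(0, c1 - r2)
    hi = np.minimum(r1, c1)
    lens = hi - lo + 1
    m = a.size
    row = np.repeat(np.arange(m), lens)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    k = lo[row] + (np.arange(lens.sum()) - offsets[row])
    log_pmf = (
        _log_comb(r1[row], k)
        + _log_comb(r2[row], c1[row] - k)
        - _log_comb(n[row], c1[row])
    )
    log_obs = _log_comb(r1, a) + _log_comb(r2, c1 - a) - _log_comb(n, c1)
    take = log_pmf <= log_obs[row] + _LOG_REL_TOL
    p = np.bincount(row[take], weights=np.exp(log_pmf[take]), minlength=m)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def conditional_binomial_test(x1, x2, n1, n2) -> float:
    """Exact two-sided rate comparison of counts from two libraries.

    Under the null hypothesis of equal per-read rates, ``x1`` given the
    total ``x1 + x2`` is Binomial(``x1 + x2``, ``n1 / (n1 + n2)``); the
    two-sided p-value sums outcome probabilities at most that of ``x1``.

    Raises
    ------
    ValueError
        If counts are invalid, a library size is non-positive, or
        ``x1 + x2 == 0`` (the conditional test is undefined — callers must
        pre-filter zero-total rows).
    """
    x1 = _check_count("x1", x1)
    x2 = _check_count("x2", x2)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    if x1 + x2 == 0:
        raise ValueError("conditional test undefined for x1 + x2 == 0")
    return float(
        conditional_binomial_many(
            np.array([x1]), np.array([x2]), float(n1), float(n2)
        )[0]
    )


def conditional_binomial_many(x1, x2, n1: float, n2: float) -> np.ndarray:
    """Vectorised conditional binomial test; rows with zero total give NaN."""
    x1 = np.asarray(x1, dtype=np.int64)
    x2 = np.asarray(x2, dtype=np.int64)
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    tot = x1 + x2
    out = np.full(x1.shape, np.nan)
    ok = tot > 0
    idx = np.nonzero(ok)[0]
    p0 = float(n1) / (float(n1) + float(n2))
    for start in range(0, idx.size, _CHUNK):
        rows = idx[start : start + _CHUNK]
        out[rows] = _binom_chunk(x1[rows], tot[rows], p0)
    return out


def _binom_chunk(x, n, p0: float) -> np.ndarray:
    m = x.size
    lens = n + 1
    row = np.repeat(np.arange(m), lens)
    offsets = np.concatenate([[0], np.cumsum(lens)])
    k = np.arange(lens.sum()) - offsets[row]
    log_p0 = np.log(p0)
    log_q0 = np.log1p(-p0)
    log_pmf = _log_comb(n[row], k) + k * log_p0 + (n[row] - k) * log_q0
    log_obs = _log_comb(n, x) + x * log_p0 + (n - x) * log_q0
    take = log_pmf <= log_obs[row] + _LOG_REL_TOL
    p = np.bincount(row[take], weights=np.exp(log_pmf[take]), minlength=m)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, returned in input order.

    ``q_(i) = min_{j >= i} (p_(j) * n / j)`` over the sorted p-values,
    capped at 1. Guarantees ``q >= p`` elementwise and preserves the order
    of the p-values (monotone).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("p must be a non-empty 1-D vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(n)
    q[order] = q_sorted
    return q
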