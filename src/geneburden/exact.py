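"""Exact conditional tests on genotype and allele count tables.

Two primitives drive the whole association layer:

* ``hwe_exact_pvalue`` — the exact conditional test for departure from
  Hardy-Weinberg proportions. Conditional on the observed minor-allele count
  ``m`` in ``n`` diploid individuals, the heterozygote count ``h`` follows

      P(h | n, m) = C(n; h, (m-h)/2, n-(m+h)/2) * 2**h / C(2n, m)

  over the ``h`` with the same parity as ``m``. The two-sided p-value sums
  the probabilities of every configuration no more likely than the observed
  one (probability-mass criterion).

* ``fisher_exact_2xk`` — the exact test of independence for a 2xK table
  (K = 2 or 3) with fixed margins. Table probabilities are multivariate
  hypergeometric; the two-sided p-value again sums probabilities <= that of
  the observed table. For K = 2 this is Fisher's classic test; for K = 3 it
  is the Freeman-Halton extension, computed by full vectorized enumeration
  of the (row1) cell grid.

Both use a shared log-factorial lookup table, so a single call costs little
more than the enumeration itself; pooled gene-level tables with a few
thousand observations remain fast.

Ties in the probability-mass criterion are resolved with a relative
tolerance of 1e-7 (the convention R's ``fisher.test`` uses), so symmetric
configurations with mathematically equal probabilities are always included.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .core import GeneBurdenError

#: Relative tolerance for "no more probable than observed" comparisons.
REL_TOL = 1e-7

_LOGFACT = np.zeros(1)


def _logfact(n: int) -> np.ndarray:
    """Lookup table of log(k!) for k = 0..n (grown on demand, cached)."""
    global _LOGFACT
    if _LOGFACT.size <= n:
        from scipy.special import gammaln

        _LOGFACT = gammaln(np.arange(max(n + 1, 2 * _LOGFACT.size), dtype=np.float64) + 1.0)
    return _LOGFACT


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact p-value for departure from Hardy-Weinberg proportions.

    Parameters are genotype counts with missing genotypes already dropped.
    Monomorphic sites return 1.0. Invariant under swapping ref/alt labels.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise GeneBurdenError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise GeneBurdenError("need at least one called genotype")
    n_alt = 2 * n_hom_alt + n_het
    m = min(n_alt, 2 * n - n_alt)  # minor-allele count
    if m == 0:
        return 1.0
    return _hwe_cached(n, m, n_het)


@lru_cache(maxsize=1 << 18)
def _hwe_cached(n: int, m: int, n_het: int) -> float:
    lf = _logfact(2 * n)
    h = np.arange(m % 2, m + 1, 2)  # feasible het counts, same parity as m
    hom_minor = (m - h) // 2
    hom_major = n - h - hom_minor
    logp = (
        lf[n]
        - lf[h]
        - lf[hom_minor]
        - lf[hom_major]
        + h * np.log(2.0)
        - (lf[2 * n] - lf[m] - lf[2 * n - m])
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(h, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + REL_TOL)].sum()))


# ---------------------------------------------------------------------------
# Fisher exact test for 2xK tables
# ---------------------------------------------------------------------------


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided exact p for a 2xK count table (K in {2, 3} after dropping
    all-zero columns).

    Zero-margin (degenerate) tables — an empty row, or fewer than two
    populated columns — carry no information about association and return 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise GeneBurdenError(f"expected a 2xK table, got shape {t.shape}")
    if (t < 0).any():
        raise GeneBurdenError("table counts must be non-negative")
    t = t[:, t.sum(axis=0) > 0]  # empty categories carry no information
    if t.shape[1] < 2 or (t.sum(axis=1) == 0).any():
        return 1.0
    if t.shape[1] > 3:
        raise GeneBurdenError(f"only 2x2 and 2x3 tables supported, got K={t.shape[1]}")
    return _fisher_cached(tuple(t[0]), tuple(t[1]))


@lru_cache(maxsize=1 << 17)
def _fisher_cached(row0: tuple, row1: tuple) -> float:
    t = np.array([row0, row1], dtype=np.int64)
    return _fisher_2x2(t) if t.shape[1] == 2 else _fisher_2x3(t)


#: Margin classes up to this grand total get their full p-value grid cached.
_GRID_CACHE_MAX_N = 120


def _pvalues_from_probs(probs: np.ndarray) -> np.ndarray:
    """Two-sided p for every outcome of one conditional distribution.

    Sorting the outcome probabilities once gives, for each outcome, the
    cumulative mass of all outcomes with probability <= its own (with the
    REL_TOL tie rule) — the probability-mass two-sided p-value.
    """
    order = np.argsort(probs, kind="stable")
    sorted_p = probs[order]
    csum = np.cumsum(sorted_p)
    idx = np.searchsorted(sorted_p, probs * (1.0 + REL_TOL), side="right") - 1
    return np.minimum(csum[idx], 1.0)


def table_is_degenerate(table: np.ndarray) -> bool:
    """True when a table has a zero row margin or <2 populated columns."""
    t = np.asarray(table, dtype=np.int64)
    t = t[:, t.sum(axis=0) > 0]
    return t.shape[1] < 2 or (t.sum(axis=1) == 0).any()


def _grid_2x2(r1: int, r2: int, c1: int, c2: int) -> tuple[int, np.ndarray]:
    """(lo, p-values indexed by first-cell count a - lo) for fixed margins."""
    n = r1 + r2
    lf = _logfact(n)
    lo, hi = max(0, r1 - c2), min(r1, c1)
    a = np.arange(lo, hi + 1)
    logp = (
        lf[c1] - lf[a] - lf[c1 - a]
        + lf[c2] - lf[r1 - a] - lf[c2 - (r1 - a)]
        - (lf[n] - lf[r1] - lf[r2])
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    return lo, _pvalues_from_probs(probs)


def _grid_2x3(r1: int, r2: int, c1: int, c2: int, c3: int) -> np.ndarray:
    """p-values indexed by the first-row cells (a, b) for fixed margins."""
    n = r1 + r2
    lf = _logfact(n)
    a = np.arange(0, min(r1, c1) + 1)
    b = np.arange(0, min(r1, c2) + 1)
    c = r1 - a[:, None] - b[None, :]
    ok = (c >= 0) & (c <= c3)
    c_safe = np.where(ok, c, 0)
    logp = (
        (lf[c1] - lf[a] - lf[c1 - a])[:, None]
        + (lf[c2] - lf[b] - lf[c2 - b])[None, :]
        + lf[c3] - lf[c_safe] - lf[c3 - c_safe]
        - (lf[n] - lf[r1] - lf[r2])
    )
    flat = np.exp(logp[ok] - logp[ok].max())
    flat /= flat.sum()
    grid = np.full(ok.shape, np.nan)
    grid[ok] = _pvalues_from_probs(flat)
    return grid


_grid_2x2_cached = lru_cache(maxsize=512)(_grid_2x2)
_grid_2x3_cached = lru_cache(maxsize=128)(_grid_2x3)


def _fisher_2x2(t: np.ndarray) -> float:
    r1, r2 = (int(x) for x in t.sum(axis=1))
    c1, c2 = (int(x) for x in t.sum(axis=0))
    fn = _grid_2x2_cached if r1 + r2 <= _GRID_CACHE_MAX_N else _grid_2x2
    lo, pvals = fn(r1, r2, c1, c2)
    return float(pvals[int(t[0, 0]) - lo])


def _fisher_2x3(t: np.ndarray) -> float:
    r1, r2 = (int(x) for x in t.sum(axis=1))
    c1, c2, c3 = (int(x) for x in t.sum(axis=0))
    fn = _grid_2x3_cached if r1 + r2 <= _GRID_CACHE_MAX_N else _grid_2x3
    grid = fn(r1, r2, c1, c2, c3)
    return float(grid[int(t[0, 0]), int(t[0, 1])])
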