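"""Independent reference implementations used only to verify the package.

Everything here is deliberately brute force: exact rational arithmetic
(fractions) or naive enumeration, sharing no code with the package's
implementations beyond the tie-breaking convention (inclusion of outcomes
with probability <= observed * (1 + 1e-7)).
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np

#: Same tie tolerance as the implementation, in exact arithmetic.
TIE_TOL = Fraction(10**7 + 1, 10**7)


def hwe_pvalue_fraction(n_hom_ref: int, n_het: int, n_hom_alt: int) -> Fraction:
    """Exact-rational two-sided HWE p by full enumeration of het counts."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    m = min(n_alt, 2 * n - n_alt)
    if m == 0:
        return Fraction(1)
    weights: dict[int, Fraction] = {}
    for h in range(m % 2, m + 1, 2):
        hom_minor = (m - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        weights[h] = Fraction(
            math.factorial(n),
            math.factorial(h) * math.factorial(hom_minor) * math.factorial(hom_major),
        ) * 2**h
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return sum(p for p in probs.values() if p <= p_obs * TIE_TOL)


def _tables_with_margins(row1_total: int, col_totals: list[int]):
    """Yield all first-row fillings compatible with the margins."""

    def rec(j: int, remaining: int, cells: list[int]):
        if j == len(col_totals) - 1:
            if remaining <= col_totals[j]:
                yield cells + [remaining]
            return
        for x in range(min(remaining, col_totals[j]) + 1):
            yield from rec(j + 1, remaining - x, cells + [x])

    yield from rec(0, row1_total, [])


def fisher_pvalue_fraction(table) -> Fraction:
    """Exact-rational two-sided Fisher p for a 2xK table by enumerating all
    tables with the observed margins (multivariate hypergeometric law)."""
    t = np.asarray(table, dtype=int)
    r1 = int(t[0].sum())
    cols = [int(c) for c in t.sum(axis=0)]
    n = int(t.sum())
    denom = math.comb(n, r1)
    probs: dict[tuple, Fraction] = {}
    for cells in _tables_with_margins(r1, cols):
        num = 1
        for x, c in zip(cells, cols):
            num *= math.comb(c, x)
        probs[tuple(cells)] = Fraction(num, denom)
    p_obs = probs[tuple(int(x) for x in t[0])]
    return sum(p for p in probs.values() if p <= p_obs * TIE_TOL)


def bh_stepup_reference(pvalues) -> np.ndarray:
    """Textbook BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, order-preserved."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / (np.arange(m) + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def trend_chi2_by_expansion(table, scores) -> float:
    """N * r^2 computed by expanding the table into individual observations
    and using scipy's Pearson correlation (independent of the count algebra)."""
    from scipy import stats

    t = np.asarray(table, dtype=int)
    s = np.asarray(scores, dtype=float)
    ys, xs = [], []
    for i in range(2):
        for j in range(t.shape[1]):
            ys.extend([i] * t[i, j])
            xs.extend([s[j]] * t[i, j])
    r = stats.pearsonr(ys, xs).statistic
    return len(ys) * r**2


def carrier_counts_by_scan(gm) -> dict[str, int]:
    """Per-sample carrier burden by a naive per-cell scan."""
    out = {s: 0 for s in gm.samples}
    for i in range(gm.n_variants):
        for j, s in enumerate(gm.samples):
            if gm.dosages[i, j] >= 1:
                out[s] += 1
    return out
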