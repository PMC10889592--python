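"""Gene-set-level burden analysis: per-individual variant accumulation and
the chi-square test for linear trend across burden intervals.

Each individual's burden is the number of panel variant sites at which they
carry at least one alternative allele (carrier mode; allele mode counts
alleles instead). Individuals are binned by burden, and the 2xK table of
group x bin occupancy is tested for a linear trend with a Cochran-Armitage
style statistic: chi2 = N * r^2, where r is the Pearson correlation between
the group indicator and the column score over the N individuals, referred
to a chi-square distribution with 1 df. The statistic is invariant under
affine rescaling of the scores.

A Wilcoxon rank-sum test on the raw (unbinned) burdens is computed alongside
as a sensitivity check; the binned trend test is the headline statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, UsageError
from scipy import stats


@dataclass
class BurdenProfile:
    """Per-individual variant burden with group labels."""

    per_sample_count: dict[str, int]
    group_of: dict[str, str]
    counting_mode: str  # "carrier" | "allele"

    def by_group(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for s, c in self.per_sample_count.items():
            out.setdefault(self.group_of[s], []).append(c)
        return {g: np.asarray(v) for g, v in out.items()}


@dataclass
class TrendTestResult:
    """Chi-square linear-trend test on a 2xK binned burden table."""

    chi2: float
    df: int
    p: float
    bins: list[float]
    table: np.ndarray
    scores: list[float]
    degenerate: bool = False


def per_individual_burden(gm: GenotypeMatrix, mode: str = "carrier") -> BurdenProfile:
    """Count each sample's burden over the matrix; MISSING contributes 0."""
    if mode == "carrier":
        counts = (gm.dosages >= 1).sum(axis=0)
    elif mode == "allele":
        counts = np.where(gm.dosages == MISSING, 0, gm.dosages).sum(axis=0)
    else:
        raise UsageError(f"unknown counting mode {mode!r}")
    return BurdenProfile(
        per_sample_count={s: int(c) for s, c in zip(gm.samples, counts)},
        group_of=dict(gm.groups),
        counting_mode=mode,
    )


def auto_edges(values: np.ndarray, n_bins: int = 5) -> list[float]:
    """K equal-width bin edges spanning the observed burden range."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:  # all samples identical: widen to a unit bin
        hi = lo + 1.0
    return list(np.linspace(lo, hi, n_bins + 1))


def bin_burden(
    profile: BurdenProfile,
    edges: Sequence[float] | None = None,
    groups: tuple[str, str] | None = None,
    n_bins: int = 5,
) -> tuple[np.ndarray, list[float], tuple[str, str]]:
    """Bin per-sample burdens into a 2xK group x interval table.

    Bins are half-open except the last, which is closed (numpy histogram
    convention). Samples outside the edge range land in the nearest terminal
    bin, with a warning.
    """
    if groups is None:
        labels = [g for g in dict.fromkeys(profile.group_of.values())]
        if len(labels) != 2:
            raise UsageError("profile must contain exactly two groups, or pass groups=")
        groups = (labels[0], labels[1])
    by_group = profile.by_group()
    for g in groups:
        if g not in by_group:
            raise UsageError(f"no samples with group label {g!r}")
    values = np.concatenate([by_group[g] for g in groups])
    if edges is None:
        edges = auto_edges(values, n_bins=n_bins)
    edges = [float(e) for e in edges]
    if len(edges) < 3:
        raise UsageError("need at least 2 bins (3 edges)")
    if any(a >= b for a, b in zip(edges, edges[1:])):
        raise UsageError("bin edges must be strictly increasing")
    if values.min() < edges[0] or values.max() > edges[-1]:
        warnings.warn("burden outside bin range; clamping to terminal bins")
    table = np.zeros((2, len(edges) - 1), dtype=np.int64)
    for i, g in enumerate(groups):
        clamped = np.clip(by_group[g], edges[0], edges[-1])
        table[i], _ = np.histogram(clamped, bins=edges)
    return table, edges, groups


def chi2_linear_trend(
    table: np.ndarray, scores: Sequence[float] | None = None
) -> TrendTestResult:
    """Cochran-Armitage-type trend test on a 2xK table.

    ``scores`` default to 0..K-1 ranks when not given (callers binning by
    burden pass bin midpoints). chi2 = N * r^2 with r the Pearson correlation
    between group indicator and score across individuals; p from chi2(1 df).
    """
    t = np.asarray(table, dtype=np.float64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise UsageError(f"expected a 2xK table, got shape {t.shape}")
    k = t.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if s.size != k:
        raise UsageError(f"need {k} scores, got {s.size}")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    degenerate = n == 0 or (row == 0).any() or (col > 0).sum() < 2
    if not degenerate:
        # moments of (group indicator y, score x) over the N individuals
        mean_y = row[1] / n
        mean_x = (col * s).sum() / n
        var_y = mean_y * (1 - mean_y)
        var_x = (col * s**2).sum() / n - mean_x**2
        cov = (t[1] * s).sum() / n - mean_y * mean_x
        degenerate = var_x <= 0 or var_y <= 0
    if degenerate:
        return TrendTestResult(
            chi2=0.0, df=1, p=1.0, bins=[], table=t.astype(np.int64),
            scores=list(map(float, s)), degenerate=True,
        )
    chi2 = float(n * cov**2 / (var_x * var_y))
    p = float(stats.chi2.sf(chi2, df=1))
    return TrendTestResult(
        chi2=chi2, df=1, p=max(p, np.finfo(float).tiny), bins=[],
        table=t.astype(np.int64), scores=list(map(float, s)),
    )


@dataclass
class GeneSetBurdenSummary:
    """Trend test plus the per-group percentage-per-bin distribution."""

    trend: TrendTestResult
    profile: BurdenProfile
    percent_table: pd.DataFrame  # group, bin interval, percent of individuals
    wilcoxon_p: float


def run_gene_set_level(
    gm: GenotypeMatrix,
    groups: tuple[str, str],
    mode: str = "carrier",
    edges: Sequence[float] | None = None,
    n_bins: int = 5,
    scores: str | Sequence[float] = "midpoint",
) -> GeneSetBurdenSummary:
    """Burden profile -> binning -> trend test, plus summaries.

    ``scores`` may be "midpoint" (bin midpoints, the default), "rank"
    (0..K-1), or an explicit list.
    """
    sub = gm.subset_groups(groups)
    profile = per_individual_burden(sub, mode=mode)
    table, used_edges, groups = bin_burden(profile, edges=edges, groups=groups, n_bins=n_bins)
    if isinstance(scores, str):
        if scores == "midpoint":
            s = [(a + b) / 2 for a, b in zip(used_edges, used_edges[1:])]
        elif scores == "rank":
            s = list(range(table.shape[1]))
        else:
            raise UsageError(f"unknown score rule {scores!r}")
    else:
        s = list(scores)
    trend = chi2_linear_trend(table, scores=s)
    trend.bins = used_edges

    rows = []
    for i, g in enumerate(groups):
        total = table[i].sum()
        for j in range(table.shape[1]):
            rows.append(
                {
                    "group": g,
                    "bin_low": used_edges[j],
                    "bin_high": used_edges[j + 1],
                    "n": int(table[i, j]),
                    "percent": 100.0 * table[i, j] / total if total else float("nan"),
                }
            )
    by_group = profile.by_group()
    a, b = by_group[groups[0]], by_group[groups[1]]
    if a.size and b.size and (np.ptp(np.concatenate([a, b])) > 0):
        wilcoxon_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        wilcoxon_p = 1.0
    return GeneSetBurdenSummary(
        trend=trend,
        profile=profile,
        percent_table=pd.DataFrame(rows),
        wilcoxon_p=wilcoxon_p,
    )
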