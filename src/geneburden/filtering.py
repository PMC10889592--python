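"""Variant filtering cascade: panel regions, shared presence, exact HWE.

The pipeline order is fixed — region restriction, then removal of
group-exclusive variants (a guard against differential allele calling
between cohorts), then exclusion of variants departing from Hardy-Weinberg
equilibrium — and a :class:`FilterReport` ledger records the count at each
stage so every run's arithmetic can be audited.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .core import MISSING, GenePanel, GenotypeMatrix, UsageError, VariantKey
from .exact import hwe_exact_pvalue


class GenotypeCounts(NamedTuple):
    """Called genotype class counts at one site (missing already dropped)."""

    n_hom_ref: int
    n_het: int
    n_hom_alt: int

    @property
    def total(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt


def genotype_counts(dosage_row: np.ndarray) -> GenotypeCounts:
    """Tally 0/1/2 dosages in one variant row, ignoring MISSING."""
    d = np.asarray(dosage_row)
    return GenotypeCounts(
        int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
    )


@dataclass
class FilterReport:
    """Stage-wise variant-count ledger for one pipeline run.

    Invariant: ``n_final == n_after_shared - n_hwe_excluded`` and counts are
    non-increasing through the cascade.
    """

    n_input: int = 0
    n_after_region: int = 0
    n_after_shared: int = 0
    n_hwe_excluded: int = 0
    n_final: int = 0
    excluded: list[tuple[VariantKey, str, str]] = field(default_factory=list)
    # (key, stage, reason) — reason carries the HWE p-value for that stage

    def validate(self) -> None:
        if self.n_final != self.n_after_shared - self.n_hwe_excluded:
            raise AssertionError("filter ledger inconsistent: final != shared - hwe")
        seq = [self.n_input, self.n_after_region, self.n_after_shared, self.n_final]
        if any(a < b for a, b in zip(seq, seq[1:])):
            raise AssertionError(f"filter counts must be non-increasing: {seq}")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_region": self.n_after_region,
            "n_after_shared": self.n_after_shared,
            "n_hwe_excluded": self.n_hwe_excluded,
            "n_final": self.n_final,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def write_excluded_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("variant\tstage\treason\n")
            for key, stage, reason in self.excluded:
                fh.write(f"{key}\t{stage}\t{reason}\n")

    def log_lines(self) -> list[str]:
        return [
            f"variants after cohort join: {self.n_input}",
            f"variants within panel regions: {self.n_after_region}",
            f"variants present in every group: {self.n_after_shared}",
            f"variants excluded for HWE departure: {self.n_hwe_excluded}",
            f"final analysis matrix: {self.n_final} variants",
        ]


def filter_by_regions(
    gm: GenotypeMatrix, panel: GenePanel
) -> tuple[GenotypeMatrix, dict[VariantKey, list[str]]]:
    """Keep variants inside >=1 panel interval; map each to its gene(s).

    A 1-based VCF position ``pos`` falls in a 0-based half-open interval
    [start, end) when ``pos - 1 in [start, end)``. A variant overlapping
    several genes maps to each of them.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for gene, ivs in panel.genes.items():
        for chrom, start, end in ivs:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, gene)

    keep = np.zeros(gm.n_variants, dtype=bool)
    assignment: dict[VariantKey, list[str]] = {}
    for i, v in enumerate(gm.variants):
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        hits = sorted({iv.data for iv in tree.at(v.pos - 1)})
        if hits:
            keep[i] = True
            assignment[v] = hits
    return gm.subset_variants(keep), assignment


def shared_presence_filter(
    gm: GenotypeMatrix, groups: tuple[str, str]
) -> tuple[GenotypeMatrix, list[VariantKey]]:
    """Drop variants without >=1 alt carrier in EACH of the two groups.

    Group-exclusive variants may reflect differential calling between
    cohorts rather than biology, so they are removed before testing.
    """
    idx_a = gm.sample_indices(groups[0])
    idx_b = gm.sample_indices(groups[1])
    present_a = (gm.dosages[:, idx_a] >= 1).any(axis=1)
    present_b = (gm.dosages[:, idx_b] >= 1).any(axis=1)
    keep = present_a & present_b
    excluded = [v for v, k in zip(gm.variants, keep) if not k]
    return gm.subset_variants(keep), excluded


def hwe_filter(
    gm: GenotypeMatrix,
    alpha: float = 0.05,
    population: str | None = None,
) -> tuple[GenotypeMatrix, list[tuple[VariantKey, float]]]:
    """Remove variants whose exact HWE p-value falls below ``alpha``.

    ``population`` selects the samples the test is computed on: ``None``
    (default) uses every sample in the matrix; a group label restricts to
    that group. Missing genotypes are dropped per site (complete case).
    """
    if not 0.0 < alpha < 1.0:
        raise UsageError(f"alpha must be in (0, 1), got {alpha}")
    if population is None:
        sub = gm.dosages
    else:
        sub = gm.dosages[:, gm.sample_indices(population)]
    if sub.shape[1] == 0:
        raise UsageError("empty population for HWE filtering")

    keep = np.ones(gm.n_variants, dtype=bool)
    excluded: list[tuple[VariantKey, float]] = []
    for i in range(gm.n_variants):
        counts = genotype_counts(sub[i])
        if counts.total == 0:
            continue  # nothing called: no evidence of departure
        p = hwe_exact_pvalue(*counts)
        if p < alpha:
            keep[i] = False
            excluded.append((gm.variants[i], p))
    return gm.subset_variants(keep), excluded


def apply_filter_cascade(
    gm: GenotypeMatrix,
    panel: GenePanel,
    groups: tuple[str, str],
    hwe_alpha: float = 0.05,
    hwe_population: str | None = None,
) -> tuple[GenotypeMatrix, dict[VariantKey, list[str]], FilterReport]:
    """Region -> shared-presence -> HWE, with a full ledger."""
    report = FilterReport(n_input=gm.n_variants)
    gm_region, assignment = filter_by_regions(gm, panel)
    report.n_after_region = gm_region.n_variants
    region_kept = set(gm_region.variants)
    report.excluded.extend(
        (v, "region", "outside-panel") for v in gm.variants if v not in region_kept
    )

    gm_shared, dropped = shared_presence_filter(gm_region, groups)
    report.n_after_shared = gm_shared.n_variants
    report.excluded.extend((v, "shared", "group-exclusive") for v in dropped)

    gm_final, hwe_dropped = hwe_filter(gm_shared, alpha=hwe_alpha, population=hwe_population)
    report.n_hwe_excluded = len(hwe_dropped)
    report.n_final = gm_final.n_variants
    report.excluded.extend((v, "hwe", f"p={p:.3e}") for v, p in hwe_dropped)
    report.validate()

    assignment = {v: g for v, g in assignment.items() if v in set(gm_final.variants)}
    return gm_final, assignment, report
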