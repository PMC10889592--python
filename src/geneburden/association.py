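"""Case-control association tests at the variant and gene level.

Each comparison is made twice: at the *allele level* (2x2 table of
alternative vs reference allele counts) and at the *genotype level* (2x3
table of hom-ref / het / hom-alt counts). Gene-level tables pool the
per-variant tables elementwise, i.e. variant x sample observations are
stacked, which makes the gene test a burden-style collapsing test. P-values
come from exact conditional tests (see :mod:`geneburden.exact`) and each
test family — variant-allele, variant-genotype, gene-allele, gene-genotype —
is corrected separately with Benjamini-Hochberg.

Degenerate tables (a group with no called observations, or a monomorphic
category structure) are untestable: they are reported with p = q = 1 and
flagged, and they do not enter the BH family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import MISSING, GenotypeMatrix, UsageError, VariantKey
from .exact import fisher_exact_2xk, table_is_degenerate


@dataclass
class ContingencyTable:
    """2xK count table: rows are groups, columns are allele or genotype classes."""

    rows: tuple[str, str]
    cols: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, len(self.cols)):
            raise ValueError(f"counts shape {self.counts.shape} != (2, {len(self.cols)})")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def degenerate(self) -> bool:
        return table_is_degenerate(self.counts)

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        if self.rows != other.rows or self.cols != other.cols:
            raise ValueError("cannot add tables with different labels")
        return ContingencyTable(self.rows, self.cols, self.counts + other.counts)


@dataclass
class AssociationResult:
    """One tested unit (a variant or a gene) with both test families."""

    unit: VariantKey | str
    level: str  # "variant" | "gene"
    n_variants: int
    freq_by_group: dict[str, float]
    p_allele: float
    p_genotype: float
    q_allele: float = float("nan")
    q_genotype: float = float("nan")
    testable_allele: bool = True
    testable_genotype: bool = True

    def significant(self, alpha: float, family: str = "either") -> bool:
        sig_a = self.testable_allele and self.q_allele < alpha
        sig_g = self.testable_genotype and self.q_genotype < alpha
        if family == "allele":
            return sig_a
        if family == "genotype":
            return sig_g
        if family == "either":
            return sig_a or sig_g
        raise UsageError(f"unknown family {family!r}")


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

ALLELE_COLS = ("alt", "ref")
GENOTYPE_COLS = ("hom_ref", "het", "hom_alt")


def _group_rows(gm: GenotypeMatrix, variant: VariantKey, groups: tuple[str, str]):
    row = gm.variant_row(variant)
    return [row[gm.sample_indices(g)] for g in groups]


def allele_table(
    gm: GenotypeMatrix, variant: VariantKey, groups: tuple[str, str]
) -> ContingencyTable:
    """2x2 alt/ref allele counts per group; missing genotypes dropped."""
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, d in enumerate(_group_rows(gm, variant, groups)):
        called = d[d != MISSING]
        alt = int(called.sum())
        counts[i] = (alt, 2 * called.size - alt)
    return ContingencyTable(groups, ALLELE_COLS, counts)


def genotype_table(
    gm: GenotypeMatrix, variant: VariantKey, groups: tuple[str, str]
) -> ContingencyTable:
    """2x3 hom-ref/het/hom-alt counts per group; missing genotypes dropped."""
    counts = np.zeros((2, 3), dtype=np.int64)
    for i, d in enumerate(_group_rows(gm, variant, groups)):
        counts[i] = ((d == 0).sum(), (d == 1).sum(), (d == 2).sum())
    return ContingencyTable(groups, GENOTYPE_COLS, counts)


def gene_pooled_tables(
    gm: GenotypeMatrix,
    gene: str,
    assignment: Mapping[VariantKey, Sequence[str]],
    groups: tuple[str, str],
) -> tuple[ContingencyTable, ContingencyTable, int]:
    """Elementwise sums of per-variant allele and genotype tables for a gene."""
    keys = [v for v in gm.variants if gene in assignment.get(v, ())]
    if not keys:
        raise UsageError(f"gene {gene!r} has no assigned variants in the matrix")
    at = ContingencyTable(groups, ALLELE_COLS, np.zeros((2, 2), dtype=np.int64))
    gt = ContingencyTable(groups, GENOTYPE_COLS, np.zeros((2, 3), dtype=np.int64))
    for v in keys:
        at = at + allele_table(gm, v, groups)
        gt = gt + genotype_table(gm, v, groups)
    return at, gt, len(keys)


def fisher_exact(table: ContingencyTable | np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 or 2x3 table (1.0 if degenerate)."""
    counts = table.counts if isinstance(table, ContingencyTable) else table
    return fisher_exact_2xk(counts)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, q >= p."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise UsageError("p-values must lie in (0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Runners
# ---------------------------------------------------------------------------


def _count_arrays(
    gm: GenotypeMatrix, groups: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """All allele (n,2,2) and genotype (n,2,3) tables in one vectorized pass."""
    allele = np.empty((gm.n_variants, 2, 2), dtype=np.int64)
    geno = np.empty((gm.n_variants, 2, 3), dtype=np.int64)
    for i, g in enumerate(groups):
        sub = gm.dosages[:, gm.sample_indices(g)]
        n0 = (sub == 0).sum(axis=1)
        n1 = (sub == 1).sum(axis=1)
        n2 = (sub == 2).sum(axis=1)
        geno[:, i, 0], geno[:, i, 1], geno[:, i, 2] = n0, n1, n2
        alt = n1 + 2 * n2
        allele[:, i, 0] = alt
        allele[:, i, 1] = 2 * (n0 + n1 + n2) - alt
    return allele, geno


def _pooled_freqs(at: ContingencyTable) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for i, g in enumerate(at.rows):
        total = int(at.counts[i].sum())
        freqs[g] = float(at.counts[i, 0] / total) if total else float("nan")
    return freqs


def _attach_q(results: list[AssociationResult]) -> None:
    """BH within each testable family, in place."""
    for fam in ("allele", "genotype"):
        testable = [r for r in results if getattr(r, f"testable_{fam}")]
        qs = bh_fdr([getattr(r, f"p_{fam}") for r in testable])
        for r, q in zip(testable, qs):
            setattr(r, f"q_{fam}", float(q))
        for r in results:
            if not getattr(r, f"testable_{fam}"):
                setattr(r, f"q_{fam}", 1.0)


def run_variant_level(
    gm: GenotypeMatrix, groups: tuple[str, str], alpha_fdr: float = 0.05
) -> list[AssociationResult]:
    """Per-variant allele and genotype exact tests with BH per family."""
    alleles, genos = _count_arrays(gm, groups)
    results: list[AssociationResult] = []
    for i, v in enumerate(gm.variants):
        at = ContingencyTable(groups, ALLELE_COLS, alleles[i])
        gt = ContingencyTable(groups, GENOTYPE_COLS, genos[i])
        res = AssociationResult(
            unit=v,
            level="variant",
            n_variants=1,
            freq_by_group=_pooled_freqs(at),
            p_allele=fisher_exact(at),
            p_genotype=fisher_exact(gt),
            testable_allele=not at.degenerate,
            testable_genotype=not gt.degenerate,
        )
        results.append(res)
    _attach_q(results)
    return results


def run_gene_level(
    gm: GenotypeMatrix,
    assignment: Mapping[VariantKey, Sequence[str]],
    groups: tuple[str, str],
    alpha_fdr: float = 0.05,
) -> list[AssociationResult]:
    """Per-gene pooled tests over every gene with >=1 surviving variant.

    The BH family is the set of genes actually tested (genes whose variants
    were all filtered out have no p-value and are skipped).
    """
    genes = sorted({g for gs in assignment.values() for g in gs})
    alleles, genos = _count_arrays(gm, groups)
    rows_of: dict[str, list[int]] = {g: [] for g in genes}
    for i, v in enumerate(gm.variants):
        for g in assignment.get(v, ()):
            rows_of[g].append(i)
    results: list[AssociationResult] = []
    for gene in genes:
        rows = rows_of[gene]
        if not rows:
            continue
        at = ContingencyTable(groups, ALLELE_COLS, alleles[rows].sum(axis=0))
        gt = ContingencyTable(groups, GENOTYPE_COLS, genos[rows].sum(axis=0))
        n = len(rows)
        results.append(
            AssociationResult(
                unit=gene,
                level="gene",
                n_variants=n,
                freq_by_group=_pooled_freqs(at),
                p_allele=fisher_exact(at),
                p_genotype=fisher_exact(gt),
                testable_allele=not at.degenerate,
                testable_genotype=not gt.degenerate,
            )
        )
    _attach_q(results)
    return results
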