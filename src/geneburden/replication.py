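"""Replication of gene-level findings against a reference panel cohort.

Genes that reach FDR significance in the case/control discovery stage are
re-tested against an external reference panel (a 1000-Genomes-style
population), restricted to the candidate variants that are present in at
least one panel individual. The test machinery is identical to the
discovery gene-level stage (pooled allele and genotype exact tests), with
BH correction inside the candidate-gene family only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .association import (
    AssociationResult,
    _attach_q,
    _pooled_freqs,
    fisher_exact,
    gene_pooled_tables,
)
from .core import GenotypeMatrix, UsageError, VariantKey, full_join

logger = logging.getLogger(__name__)


@dataclass
class ReplicationSet:
    """Candidate genes/variants carried from discovery into replication."""

    candidate_genes: list[str]
    candidate_variants: list[VariantKey]
    panel_present: list[VariantKey]

    def __post_init__(self) -> None:
        cand = set(self.candidate_variants)
        if not set(self.panel_present) <= cand:
            raise ValueError("panel_present must be a subset of candidate_variants")


def build_replication_set(
    discovery: Sequence[AssociationResult],
    assignment: Mapping[VariantKey, Sequence[str]],
    gm_panel: GenotypeMatrix,
    alpha_fdr: float = 0.05,
    rule: str = "either",
) -> ReplicationSet:
    """Select candidate genes (significant in discovery) and their variants
    with >=1 alternative-allele carrier in the panel.

    ``rule`` decides which FDR family qualifies a gene: "either" (default),
    "allele", or "genotype".
    """
    genes = sorted(
        str(r.unit) for r in discovery if r.level == "gene" and r.significant(alpha_fdr, rule)
    )
    gene_set = set(genes)
    variants = [v for v, gs in assignment.items() if gene_set & set(gs)]
    variants.sort(key=VariantKey.sort_key)
    present = [
        v for v in variants if v in gm_panel and (gm_panel.variant_row(v) >= 1).any()
    ]
    return ReplicationSet(
        candidate_genes=genes, candidate_variants=variants, panel_present=present
    )


def run_replication(
    repl: ReplicationSet,
    gm_case: GenotypeMatrix,
    gm_panel: GenotypeMatrix,
    assignment: Mapping[VariantKey, Sequence[str]],
    alpha_fdr: float = 0.05,
) -> list[AssociationResult]:
    """Gene-level pooled exact tests, case cohort vs reference panel, over
    panel-present candidate variants only; BH within the candidate family."""
    if not repl.panel_present:
        return []
    case_groups = gm_case.group_labels()
    panel_groups = gm_panel.group_labels()
    if len(case_groups) != 1 or len(panel_groups) != 1:
        raise UsageError("case and panel matrices must each hold a single group")
    groups = (case_groups[0], panel_groups[0])

    present = set(repl.panel_present)
    case_sub = gm_case.subset_variants([v for v in gm_case.variants if v in present])
    panel_sub = gm_panel.subset_variants([v for v in gm_panel.variants if v in present])
    joined = full_join([case_sub, panel_sub])

    sub_assignment = {
        v: [g for g in assignment[v] if g in set(repl.candidate_genes)]
        for v in repl.panel_present
    }
    results: list[AssociationResult] = []
    for gene in repl.candidate_genes:
        keys = [v for v in repl.panel_present if gene in sub_assignment.get(v, ())]
        if not keys:
            logger.info("gene %s lost all variants to panel absence; dropped", gene)
            continue
        at, gt, n = gene_pooled_tables(joined, gene, sub_assignment, groups)
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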