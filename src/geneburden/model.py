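"""Model/Results interface for the full discovery + replication analysis.

``GeneSetBurdenModel`` holds the joined cohort genotype matrix, the gene
panel and the analysis settings; ``fit()`` runs the filtering cascade and
the three analysis levels (variant, gene, gene set) and returns a
``GeneSetBurdenResults`` carrying the estimates, q-values, the filter
ledger and a ``summary()`` table. ``GeneSetBurdenResults.replicate()`` runs
the reference-panel stage on the discovery candidates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import association, burden, filtering, io, replication
from .association import AssociationResult
from .burden import GeneSetBurdenSummary
from .core import GenePanel, GenotypeMatrix, UsageError, VariantKey, full_join
from .filtering import FilterReport
from .replication import ReplicationSet


class GeneSetBurdenModel:
    """Case-control gene-set burden analysis on a joined genotype matrix.

    Parameters
    ----------
    genotypes
        Joined matrix holding both cohorts (see :func:`geneburden.core.full_join`).
    panel
        Gene panel restricting and grouping the variants.
    case_group, control_group
        Group labels of the two compared cohorts.
    hwe_alpha
        Significance level of the exact Hardy-Weinberg filter (default 0.05).
    hwe_population
        Samples the HWE test runs on: None = both cohorts combined (default),
        or a single group label.
    fdr_alpha
        FDR threshold for declaring significance (default 0.05).
    burden_mode
        "carrier" (sites with >=1 alt allele, default) or "allele" (allele count).
    bin_edges, n_bins, trend_scores
        Burden-histogram binning (auto equal-width K=5 by default) and trend
        scores ("midpoint", "rank", or explicit).
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        panel: GenePanel,
        case_group: str = "AFF",
        control_group: str = "OP",
        *,
        hwe_alpha: float = 0.05,
        hwe_population: str | None = None,
        fdr_alpha: float = 0.05,
        burden_mode: str = "carrier",
        bin_edges: Sequence[float] | None = None,
        n_bins: int = 5,
        trend_scores: str | Sequence[float] = "midpoint",
        candidate_rule: str = "either",
    ) -> None:
        if not 0 < fdr_alpha < 1:
            raise UsageError(f"fdr_alpha must be in (0,1), got {fdr_alpha}")
        self.genotypes = genotypes
        self.panel = panel
        self.case_group = case_group
        self.control_group = control_group
        self.hwe_alpha = hwe_alpha
        self.hwe_population = hwe_population
        self.fdr_alpha = fdr_alpha
        self.burden_mode = burden_mode
        self.bin_edges = list(bin_edges) if bin_edges is not None else None
        self.n_bins = n_bins
        self.trend_scores = trend_scores
        self.candidate_rule = candidate_rule
        # fail fast if the labels are absent
        genotypes.sample_indices(case_group)
        genotypes.sample_indices(control_group)

    @classmethod
    def from_vcfs(
        cls,
        case_vcf: str | Path,
        control_vcf: str | Path,
        panel_bed: str | Path,
        case_group: str = "AFF",
        control_group: str = "OP",
        **kwargs,
    ) -> "GeneSetBurdenModel":
        """Read the two cohort VCFs, full-join them, and read the panel BED."""
        gm_case = io.read_cohort_vcf(case_vcf, case_group)
        gm_ctrl = io.read_cohort_vcf(control_vcf, control_group)
        joined = full_join([gm_case, gm_ctrl])
        panel = io.read_gene_panel(panel_bed)
        return cls(joined, panel, case_group=case_group, control_group=control_group, **kwargs)

    @property
    def groups(self) -> tuple[str, str]:
        return (self.case_group, self.control_group)

    def fit(self) -> "GeneSetBurdenResults":
        """Run filtering and all three analysis levels."""
        gm, assignment, report = filtering.apply_filter_cascade(
            self.genotypes,
            self.panel,
            self.groups,
            hwe_alpha=self.hwe_alpha,
            hwe_population=self.hwe_population,
        )
        variant_results = association.run_variant_level(gm, self.groups, self.fdr_alpha)
        gene_results = association.run_gene_level(gm, assignment, self.groups, self.fdr_alpha)
        gene_set = burden.run_gene_set_level(
            gm,
            self.groups,
            mode=self.burden_mode,
            edges=self.bin_edges,
            n_bins=self.n_bins,
            scores=self.trend_scores,
        )
        return GeneSetBurdenResults(
            model=self,
            matrix=gm,
            assignment=assignment,
            filter_report=report,
            variant_results=variant_results,
            gene_results=gene_results,
            gene_set=gene_set,
        )


@dataclass
class GeneSetBurdenResults:
    """Fitted discovery analysis: estimates, q-values and diagnostics."""

    model: GeneSetBurdenModel
    matrix: GenotypeMatrix
    assignment: dict[VariantKey, list[str]]
    filter_report: FilterReport
    variant_results: list[AssociationResult]
    gene_results: list[AssociationResult]
    gene_set: GeneSetBurdenSummary

    # -- frames and summaries ------------------------------------------------

    def variant_frame(self) -> pd.DataFrame:
        return io.results_to_frame(self.variant_results)

    def gene_frame(self) -> pd.DataFrame:
        df = io.results_to_frame(self.gene_results)
        return df.sort_values("q_allele", kind="stable").reset_index(drop=True)

    def significant_genes(self, family: str | None = None) -> list[str]:
        fam = family or self.model.candidate_rule
        return sorted(
            str(r.unit)
            for r in self.gene_results
            if r.significant(self.model.fdr_alpha, fam)
        )

    def summary(self) -> str:
        """Human-readable run summary (filter ledger, top genes, trend test)."""
        m = self.model
        lines = [
            "Gene-set variant burden analysis",
            "=" * 48,
            f"groups: {m.case_group} "
            f"(n={len(m.genotypes.sample_indices(m.case_group))}) vs "
            f"{m.control_group} (n={len(m.genotypes.sample_indices(m.control_group))})",
            f"panel: {m.panel.n_genes} genes; "
            f"HWE alpha={m.hwe_alpha} ({m.hwe_population or 'combined'}); "
            f"FDR alpha={m.fdr_alpha}",
            "",
            "Filter ledger",
            "-" * 48,
            *self.filter_report.log_lines(),
            "",
            f"Variant level: {len(self.variant_results)} tested, "
            f"{sum(r.significant(m.fdr_alpha) for r in self.variant_results)} significant "
            f"(FDR<{m.fdr_alpha})",
            f"Gene level: {len(self.gene_results)} genes tested, "
            f"{len(self.significant_genes())} significant (FDR<{m.fdr_alpha})",
            "",
            "Gene set level",
            "-" * 48,
            f"burden mode: {self.gene_set.profile.counting_mode}; "
            f"bins: {[round(e, 2) for e in self.gene_set.trend.bins]}",
            f"chi2 linear trend = {self.gene_set.trend.chi2:.4g} (df=1), "
            f"p = {self.gene_set.trend.p:.3g}",
            f"Wilcoxon rank-sum (unbinned, sensitivity) p = {self.gene_set.wilcoxon_p:.3g}",
        ]
        sig = self.significant_genes()
        if sig:
            lines += ["", "Significant genes", "-" * 48]
            df = self.gene_frame()
            df = df[df["unit"].isin(sig)]
            lines.append(df.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
        return "\n".join(lines)

    # -- replication ---------------------------------------------------------

    def build_replication_set(
        self, panel_matrix: GenotypeMatrix, alpha_fdr: float | None = None
    ) -> ReplicationSet:
        return replication.build_replication_set(
            self.gene_results,
            self.assignment,
            panel_matrix,
            alpha_fdr=alpha_fdr if alpha_fdr is not None else self.model.fdr_alpha,
            rule=self.model.candidate_rule,
        )

    def replicate(
        self, panel_matrix: GenotypeMatrix, alpha_fdr: float | None = None
    ) -> "ReplicationResults":
        """Re-test discovery-significant genes against a reference panel."""
        alpha = alpha_fdr if alpha_fdr is not None else self.model.fdr_alpha
        repl_set = self.build_replication_set(panel_matrix, alpha)
        gm_case = self.matrix.subset_groups([self.model.case_group])
        results = replication.run_replication(
            repl_set, gm_case, panel_matrix, self.assignment, alpha_fdr=alpha
        )
        return ReplicationResults(
            discovery=self, replication_set=repl_set, results=results, alpha_fdr=alpha
        )

    # -- output --------------------------------------------------------------

    def to_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gene_tsv": outdir / "gene_level.tsv",
            "variant_tsv": outdir / "variant_level.tsv",
            "burden_tsv": outdir / "burden_bins.tsv",
            "filter_json": outdir / "filter_report.json",
            "excluded_tsv": outdir / "excluded_variants.tsv",
            "summary_json": outdir / "summary.json",
        }
        io.write_results_table(self.gene_results, paths["gene_tsv"])
        io.write_results_table(self.variant_results, paths["variant_tsv"])
        self.gene_set.percent_table.to_csv(
            paths["burden_tsv"], sep="\t", index=False, float_format="%.6g"
        )
        self.filter_report.to_json(paths["filter_json"])
        self.filter_report.write_excluded_tsv(paths["excluded_tsv"])
        m = self.model
        summary = {
            "filter_report": self.filter_report.to_dict(),
            "fdr_alpha": m.fdr_alpha,
            "hwe_alpha": m.hwe_alpha,
            "family_sizes": {
                "variant_allele": sum(r.testable_allele for r in self.variant_results),
                "variant_genotype": sum(r.testable_genotype for r in self.variant_results),
                "gene_allele": sum(r.testable_allele for r in self.gene_results),
                "gene_genotype": sum(r.testable_genotype for r in self.gene_results),
            },
            "significant_genes": self.significant_genes(),
            "trend": {
                "chi2": self.gene_set.trend.chi2,
                "df": self.gene_set.trend.df,
                "p": self.gene_set.trend.p,
                "edges": self.gene_set.trend.bins,
                "mode": self.gene_set.profile.counting_mode,
                "wilcoxon_p": self.gene_set.wilcoxon_p,
            },
        }
        with open(paths["summary_json"], "w") as fh:
            json.dump(summary, fh, indent=2)
            fh.write("\n")
        return paths


@dataclass
class ReplicationResults:
    """Reference-panel replication of the discovery candidates."""

    discovery: GeneSetBurdenResults
    replication_set: ReplicationSet
    results: list[AssociationResult]
    alpha_fdr: float

    def replicated_genes(self, family: str | None = None) -> list[str]:
        fam = family or self.discovery.model.candidate_rule
        return sorted(
            str(r.unit) for r in self.results if r.significant(self.alpha_fdr, fam)
        )

    def frame(self) -> pd.DataFrame:
        return io.results_to_frame(self.results)

    def summary(self) -> str:
        rs = self.replication_set
        lines = [
            "Reference-panel replication",
            "=" * 48,
            f"candidate genes: {len(rs.candidate_genes)} "
            f"({', '.join(rs.candidate_genes) or 'none'})",
            f"candidate variants: {len(rs.candidate_variants)}; "
            f"present in panel: {len(rs.panel_present)}",
            f"replicated (FDR<{self.alpha_fdr}): "
            f"{', '.join(self.replicated_genes()) or 'none'}",
        ]
        if self.results:
            lines += ["", self.frame().to_string(index=False, float_format=lambda x: f"{x:.3g}")]
        return "\n".join(lines)

    def to_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "replication_tsv": outdir / "replication_gene_level.tsv",
            "replication_json": outdir / "replication.json",
        }
        io.write_results_table(self.results, paths["replication_tsv"])
        payload = {
            "candidate_genes": self.replication_set.candidate_genes,
            "n_candidate_variants": len(self.replication_set.candidate_variants),
            "n_panel_present": len(self.replication_set.panel_present),
            "replicated_genes": self.replicated_genes(),
            "fdr_alpha": self.alpha_fdr,
        }
        with open(paths["replication_json"], "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
        return paths
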