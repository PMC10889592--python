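"""Reading and writing the pipeline's file formats.

Cohort and reference-panel genotypes come in as VCF 4.x (plain or
bgzip/tabix) and are parsed with cyvcf2; gene panels are BED-like 4-column
TSVs (chrom, start, end, gene; 0-based half-open). Multi-allelic VCF records
are split into one matrix row per alternative allele; phased genotype
separators are collapsed; a genotype with any missing allele becomes
MISSING. Results go out as TSV with a fixed column layout so runs are
byte-reproducible.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    GenePanel,
    GenotypeMatrix,
    InputFormatError,
    UsageError,
    VariantKey,
    make_variant_key,
    normalize_chrom,
)

if TYPE_CHECKING:
    from .association import AssociationResult

_DNA = set("ACGTN")


def read_cohort_vcf(path: str | Path, group_label: str) -> GenotypeMatrix:
    """Read a (possibly multi-sample) VCF into a dosage matrix.

    Every sample is assigned ``group_label``. Records on non-canonical
    contigs or with symbolic/star alternative alleles are skipped with a
    warning. Raises :class:`InputFormatError` when the file cannot be parsed
    or carries no GT format field.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise InputFormatError(f"cannot open VCF {path!r}: {exc}") from exc
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise InputFormatError(f"VCF {path!r} has no GT format field")

    samples = list(vcf.samples)
    if not samples:
        raise InputFormatError(f"VCF {path!r} has no sample columns")

    keys: list[VariantKey] = []
    rows: list[np.ndarray] = []
    seen: set[VariantKey] = set()
    for rec in vcf:
        try:
            chrom = normalize_chrom(rec.CHROM)
        except InputFormatError:
            warnings.warn(f"skipping record on unsupported contig {rec.CHROM!r}")
            continue
        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([g[:-1] for g in gts], dtype=np.int16)  # drop phase flag
        if alleles.shape[1] != 2:
            raise InputFormatError(
                f"non-diploid GT at {rec.CHROM}:{rec.POS} in {path!r}"
            )
        any_missing = (alleles < 0).any(axis=1)
        for alt_idx, alt in enumerate(rec.ALT, start=1):
            if alt in (".", "*") or alt.startswith("<") or not set(alt.upper()) <= _DNA:
                warnings.warn(f"skipping non-sequence alt {alt!r} at {rec.CHROM}:{rec.POS}")
                continue
            key = make_variant_key(chrom, rec.POS, rec.REF, alt)
            if key in seen:
                raise InputFormatError(f"duplicate variant {key} in {path!r}")
            seen.add(key)
            dos = (alleles == alt_idx).sum(axis=1).astype(np.int8)
            dos[any_missing] = MISSING
            keys.append(key)
            rows.append(dos)

    dosages = np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.int8)
    return GenotypeMatrix(
        variants=keys,
        samples=samples,
        groups={s: group_label for s in samples},
        dosages=dosages,
    )


def read_gene_panel(path: str | Path) -> GenePanel:
    """Read a BED-like panel file (chrom, start, end, gene) into a GenePanel.

    Overlapping intervals of the same gene are merged; 0-based half-open
    coordinates are kept as-is.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            comment="#",
            names=["chrom", "start", "end", "gene"],
            dtype={"chrom": str, "gene": str},
        )
    except Exception as exc:
        raise InputFormatError(f"cannot parse panel file {path!r}: {exc}") from exc
    if df.empty:
        raise InputFormatError(f"panel file {path!r} has no intervals")
    if df["gene"].isna().any():
        raise InputFormatError(f"panel file {path!r} is missing the gene column")
    return GenePanel.from_intervals(
        (str(r.chrom), int(r.start), int(r.end), str(r.gene)) for r in df.itertuples()
    )


def bundled_panel_path() -> Path:
    """Path to the bundled synthetic 457-gene placeholder panel BED.

    A deterministic, synthetic stand-in (generic PANELnnn symbols on evenly
    spaced intervals) matching the size of a curated skeletal-homeostasis
    gene set; real analyses should supply their own curated panel.
    """
    return Path(__file__).parent / "data" / "synthetic_panel_457.bed"


def write_panel_bed(panel: GenePanel, path: str | Path) -> None:
    """Write a GenePanel back out as a 4-column BED, sorted for determinism."""
    rows = [
        (chrom, start, end, gene)
        for gene, ivs in panel.genes.items()
        for chrom, start, end in ivs
    ]
    from .core import chrom_sort_key

    rows.sort(key=lambda r: (chrom_sort_key(r[0]), r[1], r[2], r[3]))
    with open(path, "w") as fh:
        for chrom, start, end, gene in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


# ---------------------------------------------------------------------------
# VCF writing (used by the simulator and for matrix round-trips)
# ---------------------------------------------------------------------------

_GT_UNPHASED = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_GT_PHASED = {0: "0|0", 1: "0|1", 2: "1|1", MISSING: ".|."}


def write_vcf(gm: GenotypeMatrix, path: str | Path, *, phased: bool = False) -> None:
    """Write a dosage matrix as a minimal GT-only VCF 4.2.

    The header is fixed (no dates, no tool versions), so identical matrices
    produce byte-identical files. Heterozygotes are written 0/1 (or 0|1);
    phase information is not modelled.
    """
    chroms: list[str] = []
    for v in gm.variants:
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    gt = _GT_PHASED if phased else _GT_UNPHASED
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=geneburden\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.samples) + "\n")
        for i, v in enumerate(gm.variants):
            cells = "\t".join(gt[int(d)] for d in gm.dosages[i])
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{cells}\n")


# ---------------------------------------------------------------------------
# Result tables
# ---------------------------------------------------------------------------

def results_to_frame(results: Sequence["AssociationResult"]) -> pd.DataFrame:
    """Flatten association results into the standard output table.

    Columns: unit, level, n_variants, freq_<group> (fractions), p/q for the
    allele and genotype families, and per-family testability flags.
    """
    groups: list[str] = []
    for r in results:
        for g in r.freq_by_group:
            if g not in groups:
                groups.append(g)
    rows = []
    for r in results:
        row: dict[str, object] = {
            "unit": str(r.unit),
            "level": r.level,
            "n_variants": r.n_variants,
        }
        for g in groups:
            row[f"freq_{g}"] = r.freq_by_group.get(g, np.nan)
        row.update(
            p_allele=r.p_allele,
            q_allele=r.q_allele,
            p_genotype=r.p_genotype,
            q_genotype=r.q_genotype,
            testable_allele=r.testable_allele,
            testable_genotype=r.testable_genotype,
        )
        rows.append(row)
    cols = ["unit", "level", "n_variants"] + [f"freq_{g}" for g in groups] + [
        "p_allele", "q_allele", "p_genotype", "q_genotype",
        "testable_allele", "testable_genotype",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_results_table(results: Sequence["AssociationResult"], path: str | Path) -> None:
    """Write association results as a TSV (one analysis level per file).

    Frequencies are printed as percentages rounded to 6 significant digits;
    p and q to 6 significant digits; counts exactly.
    """
    levels = {r.level for r in results}
    if len(levels) > 1:
        raise UsageError(f"results mix analysis levels: {sorted(levels)}")
    df = results_to_frame(results)
    for col in df.columns:
        if col.startswith("freq_"):
            df[col] = df[col] * 100.0
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV (frequencies as percentages)."""
    return pd.read_csv(path, sep="\t")
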