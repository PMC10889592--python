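"""Core data model: variant keys, genotype matrices and gene panels.

The pipeline's central container is a variants x samples matrix of
alternative-allele dosages (0/1/2, with a distinct MISSING sentinel), carrying
a group label per sample (e.g. case cohort, control cohort, reference panel).
All coordinates are GRCh37-style: VCF positions are 1-based, panel intervals
are 0-based half-open (BED convention); conversion happens only at the
region-filter boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

#: Sentinel for an uncalled genotype in a dosage matrix.
MISSING: int = -1

#: Accepted contigs, in canonical sort order.
CANONICAL_CHROMS: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + ("X", "Y", "MT")

_CHROM_ORDER: dict[str, int] = {c: i for i, c in enumerate(CANONICAL_CHROMS)}


class GeneBurdenError(Exception):
    """Base class for pipeline errors."""


class InputFormatError(GeneBurdenError):
    """Malformed or unsupported input file."""


class UsageError(GeneBurdenError):
    """Invalid arguments or configuration."""


def normalize_chrom(chrom: str) -> str:
    """Strip a 'chr' prefix and map 'M' to 'MT'.

    Raises :class:`InputFormatError` for contigs outside 1-22, X, Y, MT.
    """
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c == "M":
        c = "MT"
    if c not in _CHROM_ORDER:
        raise InputFormatError(f"unsupported contig {chrom!r} (expected 1-22, X, Y, MT)")
    return c


class VariantKey(NamedTuple):
    """Biallelic variant identity: normalized chrom, 1-based pos, ref, alt.

    Multi-allelic records are split upstream, so ``alt`` is always a single
    allele and a key is unique within any :class:`GenotypeMatrix`.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def sort_key(self) -> tuple[int, int, str, str]:
        return (_CHROM_ORDER[self.chrom], self.pos, self.ref, self.alt)

    def __str__(self) -> str:  # e.g. "1:1000:A>G"
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def from_string(cls, s: str) -> "VariantKey":
        chrom, pos, change = s.split(":")
        ref, alt = change.split(">")
        return cls(chrom, int(pos), ref, alt)


def make_variant_key(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Validated constructor used by readers and the simulator."""
    chrom = normalize_chrom(chrom)
    ref, alt = ref.upper(), alt.upper()
    if pos < 1:
        raise InputFormatError(f"position must be >= 1, got {pos}")
    if ref == alt:
        raise InputFormatError(f"ref and alt identical at {chrom}:{pos} ({ref})")
    return VariantKey(chrom, pos, ref, alt)


@dataclass
class GenotypeMatrix:
    """Variants x samples alternative-allele dosage matrix with group labels.

    ``dosages`` holds 0/1/2 alt-allele counts, :data:`MISSING` (-1) for
    uncalled genotypes. Genotypes are treated as unphased; phased input is
    collapsed to dosages at read time.
    """

    variants: list[VariantKey]
    samples: list[str]
    groups: dict[str, str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.variants), len(self.samples)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} != "
                f"({len(self.variants)}, {len(self.samples)})"
            )
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant keys in matrix")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample IDs in matrix")
        missing_groups = [s for s in self.samples if s not in self.groups]
        if missing_groups:
            raise ValueError(f"samples without group label: {missing_groups[:5]}")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or MISSING")
        self._index: dict[VariantKey, int] = {v: i for i, v in enumerate(self.variants)}
        self._group_cols: dict[str, np.ndarray] = {}

    # -- basic views ---------------------------------------------------------

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def variant_row(self, key: VariantKey) -> np.ndarray:
        try:
            return self.dosages[self._index[key]]
        except KeyError:
            raise KeyError(f"variant {key} not in matrix") from None

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._index

    def group_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.groups[s], None)
        return list(seen)

    def sample_indices(self, group: str) -> np.ndarray:
        """Column indices of the samples in ``group`` (cached)."""
        idx = self._group_cols.get(group)
        if idx is None:
            idx = np.array(
                [i for i, s in enumerate(self.samples) if self.groups[s] == group], dtype=int
            )
            if idx.size == 0:
                raise UsageError(f"no samples with group label {group!r}")
            self._group_cols[group] = idx
        return idx

    # -- subsetting ----------------------------------------------------------

    def subset_variants(self, keep: Sequence[VariantKey] | np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to ``keep`` (a key list or boolean mask)."""
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            rows = np.flatnonzero(keep)
        else:
            rows = np.array([self._index[k] for k in keep], dtype=int)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in rows],
            samples=list(self.samples),
            groups=dict(self.groups),
            dosages=self.dosages[rows].copy(),
        )

    def subset_groups(self, groups: Iterable[str]) -> "GenotypeMatrix":
        wanted = set(groups)
        cols = [i for i, s in enumerate(self.samples) if self.groups[s] in wanted]
        if not cols:
            raise UsageError(f"no samples in groups {sorted(wanted)}")
        samples = [self.samples[i] for i in cols]
        return GenotypeMatrix(
            variants=list(self.variants),
            samples=samples,
            groups={s: self.groups[s] for s in samples},
            dosages=self.dosages[:, cols].copy(),
        )


def full_join(matrices: Sequence[GenotypeMatrix]) -> GenotypeMatrix:
    """Outer join of cohort matrices on variant keys.

    A variant absent from a cohort's call set is imputed as homozygous
    reference (dosage 0) for that cohort's samples: cohorts are assumed
    called on the same capture, and the downstream shared-presence filter
    guards against differential-calling artifacts. Variants come out sorted
    by (chrom, pos, ref, alt); sample IDs must be disjoint across inputs.
    """
    if not matrices:
        raise UsageError("full_join needs at least one matrix")
    samples: list[str] = []
    groups: dict[str, str] = {}
    for m in matrices:
        for s in m.samples:
            if s in groups:
                raise UsageError(f"duplicate sample ID across cohorts: {s!r}")
            groups[s] = m.groups[s]
        samples.extend(m.samples)

    keys = sorted({v for m in matrices for v in m.variants}, key=VariantKey.sort_key)
    key_row = {k: i for i, k in enumerate(keys)}
    out = np.zeros((len(keys), len(samples)), dtype=np.int8)
    col = 0
    for m in matrices:
        ncol = m.n_samples
        rows = np.array([key_row[k] for k in m.variants], dtype=int)
        if rows.size:
            out[rows, col : col + ncol] = m.dosages
        col += ncol
    return GenotypeMatrix(variants=keys, samples=samples, groups=groups, dosages=out)


@dataclass
class GenePanel:
    """Named genes mapped to 0-based half-open genomic intervals."""

    genes: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, ivs in self.genes.items():
            if not ivs:
                raise ValueError(f"gene {gene!r} has no intervals")
            for chrom, start, end in ivs:
                if start >= end:
                    raise InputFormatError(
                        f"invalid interval for {gene}: {chrom}:{start}-{end} (start >= end)"
                    )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @classmethod
    def from_intervals(cls, rows: Iterable[tuple[str, int, int, str]]) -> "GenePanel":
        """Build a panel from (chrom, start, end, gene) rows, merging
        overlapping or touching intervals of the same gene."""
        by_gene: dict[str, list[tuple[str, int, int]]] = {}
        for chrom, start, end, gene in rows:
            chrom = normalize_chrom(chrom)
            start, end = int(start), int(end)
            if start >= end:
                raise InputFormatError(
                    f"invalid interval for {gene}: {chrom}:{start}-{end} (start >= end)"
                )
            by_gene.setdefault(gene, []).append((chrom, start, end))
        merged: dict[str, list[tuple[str, int, int]]] = {}
        for gene, ivs in by_gene.items():
            ivs.sort(key=lambda t: (_CHROM_ORDER[t[0]], t[1], t[2]))
            out: list[tuple[str, int, int]] = []
            for chrom, start, end in ivs:
                if out and out[-1][0] == chrom and start <= out[-1][2]:
                    prev = out[-1]
                    out[-1] = (chrom, prev[1], max(prev[2], end))
                else:
                    out.append((chrom, start, end))
            merged[gene] = out
        return cls(genes=merged)


def chrom_sort_key(chrom: str) -> int:
    """Canonical ordering index for a normalized chromosome name."""
    return _CHROM_ORDER[chrom]
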