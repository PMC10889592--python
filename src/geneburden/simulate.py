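"""Synthetic case/control/reference-panel cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes:
biallelic SNVs scattered over a panel of genes; per-variant allele
frequencies drawn from a base law, with genotypes sampled under
Hardy-Weinberg equilibrium (binomial(2, f) per individual); designated
*effect genes* whose case-cohort allele frequency is shifted; designated
*HWE violators* drawn instead from an inbreeding-distorted genotype law
(hom-ref (1-f)^2 + F f(1-f), het 2f(1-f)(1-F), hom-alt f^2 + F f(1-f),
one scalar F controlling the departure); *group-exclusive* variants carried
in only one cohort; uniform random genotype missingness in the sequenced
cohorts; and a reference panel drawn from the control-law frequencies
(standing in for an external population such as 1000 Genomes IBS).

Default cohort sizes mirror the study design the pipeline addresses: 13
cases, 27 controls, 107 panel individuals, with ~2000 SNVs over 50 genes.
Everything is a pure function of the config seed; the same seed produces
byte-identical VCFs. What the generator does NOT model: linkage
disequilibrium, haplotype phase, sequencing error, indels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
import numpy as np

from .core import (
    CANONICAL_CHROMS,
    MISSING,
    GenePanel,
    GenotypeMatrix,
    UsageError,
    VariantKey,
    full_join,
)
from .io import write_panel_bed, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass
class GeneSpec:
    """One simulated gene: symbol, locus and number of variants."""

    symbol: str
    chrom: str
    start: int  # 0-based half-open interval
    end: int
    n_variants: int


@dataclass
class SimulationConfig:
    """Everything that determines a simulated study (seed included)."""

    seed: int = 0
    n_case: int = 13
    n_control: int = 27
    n_panel: int = 107
    n_genes: int = 50
    variants_per_gene: int = 40
    base_freq_range: tuple[float, float] = (0.05, 0.5)
    freq_overrides: dict[str, float] = field(default_factory=dict)  # gene -> control f
    effect_genes: dict[str, float] = field(default_factory=dict)  # gene -> case f
    n_hwe_violators: int = 0
    hwe_inbreeding: float = 0.8
    n_group_exclusive: int = 0  # per group
    exclusive_freq: float = 0.3
    n_panel_absent: int = 0  # candidate-style variants forced absent in the panel
    missing_rate: float = 0.02
    burden_shift: float = 1.0
    genes: list[GeneSpec] | None = None  # explicit layout overrides n_genes/variants_per_gene
    case_label: str = "AFF"
    control_label: str = "OP"
    panel_label: str = "REF"

    def gene_specs(self) -> list[GeneSpec]:
        if self.genes is not None:
            return self.genes
        specs = []
        length = max(10_000, 50 * self.variants_per_gene)
        for i in range(self.n_genes):
            chrom = CANONICAL_CHROMS[i % 22]  # autosomes only
            slot = i // 22
            start = 1_000_000 + slot * (length + 100_000)
            specs.append(
                GeneSpec(f"G{i + 1:03d}", chrom, start, start + length, self.variants_per_gene)
            )
        return specs

    def validate(self) -> None:
        if min(self.n_case, self.n_control) < 1:
            raise UsageError("need at least one case and one control sample")
        lo, hi = self.base_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise UsageError(f"base_freq_range must lie inside (0,1): {self.base_freq_range}")
        for gene, f in {**self.freq_overrides, **self.effect_genes}.items():
            if not 0.0 < f < 1.0:
                raise UsageError(f"frequency for {gene!r} outside (0,1): {f}")
        if self.burden_shift <= 0:
            raise UsageError("burden_shift must be positive")
        if hi * self.burden_shift >= 1.0:
            raise UsageError(
                f"burden_shift {self.burden_shift} pushes top base frequency {hi} past 1"
            )
        if not -1.0 < self.hwe_inbreeding < 1.0:
            raise UsageError("hwe_inbreeding must lie in (-1, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise UsageError("missing_rate must lie in [0, 1)")


@dataclass
class SimulationTruth:
    """Ground-truth labels for the injected structure, recountable from the VCFs."""

    effect_gene_labels: dict[str, bool]
    hwe_violator_keys: list[VariantKey]
    group_exclusive_keys: dict[str, list[VariantKey]]  # group label -> injected keys
    panel_absent_keys: list[VariantKey]
    gene_of: dict[VariantKey, str]
    realized_counts: dict[str, dict[str, tuple[int, int]]]
    # str(key) -> {group: (alt alleles, called alleles)} as emitted

    def realized_freq(self, key: VariantKey, group: str) -> float:
        alt, total = self.realized_counts[str(key)][group]
        return alt / total if total else float("nan")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effect_gene_labels": self.effect_gene_labels,
            "hwe_violator_keys": [str(k) for k in self.hwe_violator_keys],
            "group_exclusive_keys": {
                g: [str(k) for k in ks] for g, ks in self.group_exclusive_keys.items()
            },
            "panel_absent_keys": [str(k) for k in self.panel_absent_keys],
            "gene_of": {str(k): g for k, g in self.gene_of.items()},
            "realized_counts": self.realized_counts,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedStudy:
    """In-memory result of one simulation run."""

    config: SimulationConfig
    panel: GenePanel
    case_gm: GenotypeMatrix
    control_gm: GenotypeMatrix
    panel_gm: GenotypeMatrix
    truth: SimulationTruth

    def joined(self) -> GenotypeMatrix:
        """Full join of the case and control cohorts."""
        return full_join([self.case_gm, self.control_gm])

    def observed_group_exclusive_keys(self) -> dict[str, list[VariantKey]]:
        """Recount which joined variants have carriers in only one cohort
        (includes both injected and chance exclusives)."""
        joined = self.joined()
        case_idx = joined.sample_indices(self.config.case_label)
        ctrl_idx = joined.sample_indices(self.config.control_label)
        out: dict[str, list[VariantKey]] = {
            self.config.case_label: [],
            self.config.control_label: [],
        }
        for i, v in enumerate(joined.variants):
            in_case = bool((joined.dosages[i, case_idx] >= 1).any())
            in_ctrl = bool((joined.dosages[i, ctrl_idx] >= 1).any())
            if in_case and not in_ctrl:
                out[self.config.case_label].append(v)
            elif in_ctrl and not in_case:
                out[self.config.control_label].append(v)
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit case/control/panel VCFs, the panel BED and the truth JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "case_vcf": outdir / "case.vcf",
            "control_vcf": outdir / "control.vcf",
            "panel_vcf": outdir / "panel.vcf",
            "panel_bed": outdir / "panel.bed",
            "truth_json": outdir / "truth.json",
        }
        write_vcf(self.case_gm, paths["case_vcf"])
        write_vcf(self.control_gm, paths["control_vcf"])
        write_vcf(self.panel_gm, paths["panel_vcf"], phased=True)  # 1000G-style GTs
        write_panel_bed(self.panel, paths["panel_bed"])
        self.truth.to_json(paths["truth_json"])
        return paths


def _hwe_draw(rng: np.random.Generator, f: float, n: int) -> np.ndarray:
    return rng.binomial(2, f, size=n).astype(np.int8)


def _inbred_draw(rng: np.random.Generator, f: float, F: float, n: int) -> np.ndarray:
    p_het = max(2 * f * (1 - f) * (1 - F), 0.0)
    p_alt = f * f + F * f * (1 - f)
    p_ref = max(1.0 - p_het - p_alt, 0.0)
    probs = np.array([p_ref, p_het, p_alt])
    probs = probs / probs.sum()
    return rng.choice(3, size=n, p=probs).astype(np.int8)


def simulate(config: SimulationConfig) -> SimulatedStudy:
    """Generate one study (case, control and panel cohorts plus truth).

    Deterministic given ``config``; each cohort's matrix contains only the
    variants with at least one called alternative-allele carrier in that
    cohort, mirroring what a per-cohort variant caller would emit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = config.gene_specs()
    panel = GenePanel.from_intervals((s.chrom, s.start, s.end, s.symbol) for s in specs)

    # variant scaffold: positions, alleles, base frequencies, gene assignment
    keys: list[VariantKey] = []
    gene_of: dict[VariantKey, str] = {}
    base_f: dict[VariantKey, float] = {}
    for spec in specs:
        pos = np.sort(rng.choice(np.arange(spec.start + 1, spec.end + 1), spec.n_variants, replace=False))
        for p in pos:
            ref, alt = rng.choice(4, size=2, replace=False)
            key = VariantKey(spec.chrom, int(p), str(_BASES[ref]), str(_BASES[alt]))
            f = float(rng.uniform(*config.base_freq_range))
            if spec.symbol in config.freq_overrides:
                f = config.freq_overrides[spec.symbol]
            keys.append(key)
            gene_of[key] = spec.symbol
            base_f[key] = f
    keys.sort(key=VariantKey.sort_key)

    # HWE violators and group exclusives live in null genes; panel absence can
    # hit any remaining variant (effect genes included), so replication sets
    # may genuinely lose candidate variants to the panel
    eligible = [k for k in keys if gene_of[k] not in config.effect_genes]
    n_roles = config.n_hwe_violators + 2 * config.n_group_exclusive
    if n_roles > len(eligible):
        raise UsageError("not enough null-gene variants for the requested roles")
    chosen = rng.choice(len(eligible), size=n_roles, replace=False)
    cursor = 0
    violators = {eligible[i] for i in chosen[cursor : cursor + config.n_hwe_violators]}
    cursor += config.n_hwe_violators
    excl_case = {eligible[i] for i in chosen[cursor : cursor + config.n_group_exclusive]}
    cursor += config.n_group_exclusive
    excl_ctrl = {eligible[i] for i in chosen[cursor : cursor + config.n_group_exclusive]}
    taken = violators | excl_case | excl_ctrl
    free = [k for k in keys if k not in taken]
    if config.n_panel_absent > len(free):
        raise UsageError("not enough variants left for the requested panel absences")
    panel_absent = {
        free[i] for i in rng.choice(len(free), size=config.n_panel_absent, replace=False)
    }

    n_var = len(keys)
    case = np.zeros((n_var, config.n_case), dtype=np.int8)
    ctrl = np.zeros((n_var, config.n_control), dtype=np.int8)
    pnl = np.zeros((n_var, config.n_panel), dtype=np.int8)

    for i, k in enumerate(keys):
        f = base_f[k]
        gene = gene_of[k]
        f_case = config.effect_genes.get(gene, min(f * config.burden_shift, 0.99))
        if k in excl_case:
            case[i] = _hwe_draw(rng, config.exclusive_freq, config.n_case)
            if not (case[i] >= 1).any():
                case[i, rng.integers(config.n_case)] = 1  # guarantee the injected carrier
            # control and panel stay hom-ref
        elif k in excl_ctrl:
            ctrl[i] = _hwe_draw(rng, config.exclusive_freq, config.n_control)
            if not (ctrl[i] >= 1).any():
                ctrl[i, rng.integers(config.n_control)] = 1
        elif k in violators:
            F = config.hwe_inbreeding
            case[i] = _inbred_draw(rng, f_case, F, config.n_case)
            ctrl[i] = _inbred_draw(rng, f, F, config.n_control)
            pnl[i] = _inbred_draw(rng, f, F, config.n_panel)
        else:
            case[i] = _hwe_draw(rng, f_case, config.n_case)
            ctrl[i] = _hwe_draw(rng, f, config.n_control)
            if k not in panel_absent:
                pnl[i] = _hwe_draw(rng, f, config.n_panel)

    # genotype missingness in the sequenced cohorts (panel genotypes are
    # reference-set calls and stay complete)
    if config.missing_rate > 0:
        case[rng.random(case.shape) < config.missing_rate] = MISSING
        ctrl[rng.random(ctrl.shape) < config.missing_rate] = MISSING

    def cohort_matrix(dos: np.ndarray, prefix: str, label: str, n: int) -> GenotypeMatrix:
        samples = [f"{prefix}{j + 1:03d}" for j in range(n)]
        present = (dos >= 1).any(axis=1)
        return GenotypeMatrix(
            variants=[k for k, keep in zip(keys, present) if keep],
            samples=samples,
            groups={s: label for s in samples},
            dosages=dos[present],
        )

    case_gm = cohort_matrix(case, config.case_label, config.case_label, config.n_case)
    control_gm = cohort_matrix(ctrl, config.control_label, config.control_label, config.n_control)
    panel_gm = cohort_matrix(pnl, config.panel_label, config.panel_label, config.n_panel)

    realized: dict[str, dict[str, tuple[int, int]]] = {}
    for gm in (case_gm, control_gm, panel_gm):
        label = gm.group_labels()[0]
        for i, k in enumerate(gm.variants):
            d = gm.dosages[i]
            called = d[d != MISSING]
            realized.setdefault(str(k), {})[label] = (int(called.sum()), 2 * called.size)

    truth = SimulationTruth(
        effect_gene_labels={s.symbol: s.symbol in config.effect_genes for s in specs},
        hwe_violator_keys=sorted(violators, key=VariantKey.sort_key),
        group_exclusive_keys={
            config.case_label: sorted(excl_case, key=VariantKey.sort_key),
            config.control_label: sorted(excl_ctrl, key=VariantKey.sort_key),
        },
        panel_absent_keys=sorted(panel_absent, key=VariantKey.sort_key),
        gene_of=gene_of,
        realized_counts=realized,
    )
    return SimulatedStudy(
        config=config,
        panel=panel,
        case_gm=case_gm,
        control_gm=control_gm,
        panel_gm=panel_gm,
        truth=truth,
    )


def simulate_to_files(config: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Run :func:`simulate` and write its five artifacts to ``outdir``."""
    return simulate(config).write(outdir)


# ---------------------------------------------------------------------------
# Canned scenarios for calibration studies
# ---------------------------------------------------------------------------


def make_null_scenario(
    n_reps: int, base_seed: int = 0, **overrides
) -> list[SimulationConfig]:
    """Replicated configs with no injected structure (type-I error studies)."""
    base = SimulationConfig(
        effect_genes={}, n_hwe_violators=0, n_group_exclusive=0, burden_shift=1.0,
        **overrides,
    )
    return [replace(base, seed=(base_seed + 10_007 * i) % (2**31)) for i in range(n_reps)]


def make_power_scenario(
    n_reps: int,
    base_seed: int = 0,
    n_effect_genes: int = 2,
    control_freq: float = 0.2,
    case_freq: float = 0.4,
    variants_per_gene: int = 5,
    n_case: int = 200,
    n_control: int = 200,
    **overrides,
) -> list[SimulationConfig]:
    """Replicated configs with frequency-shifted effect genes.

    ``case_freq == control_freq`` degenerates to a null scenario.
    """
    overrides.setdefault("n_genes", 20)
    base = SimulationConfig(
        n_case=n_case,
        n_control=n_control,
        variants_per_gene=variants_per_gene,
        **overrides,
    )
    effect = [f"G{i + 1:03d}" for i in range(n_effect_genes)]
    base = replace(
        base,
        freq_overrides={g: control_freq for g in effect},
        effect_genes={g: case_freq for g in effect},
    )
    return [replace(base, seed=(base_seed + 10_007 * i + 1) % (2**31)) for i in range(n_reps)]
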