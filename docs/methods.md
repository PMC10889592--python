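# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices and the known limitations of `geneburden`.

## Study design the pipeline addresses

Two small sequenced cohorts (by default labelled AFF, the cases, and OP,
the controls) are compared over a curated gene panel, with an external
reference-panel population (labelled REF) as a second comparison cohort.
The design assumes jointly captured, jointly processed exomes summarised as
called genotypes; the pipeline starts at VCF level and deliberately knows
nothing about reads, calling or annotation.

## Data model

Genotypes live in a variants × samples matrix of alternative-allele dosages
0/1/2 with a distinct MISSING sentinel. Variant identity is
(chromosome, 1-based position, ref, alt) after normalising chromosome names
(no `chr` prefix; only 1–22, X, Y, MT) and splitting multi-allelic records
into biallelic rows; phase is discarded. Panel intervals are 0-based
half-open (BED); a variant at 1-based position `pos` belongs to interval
[start, end) iff `pos − 1 ∈ [start, end)`, so conversion happens in exactly
one place.

**Cohort join.** The cohorts' variant sets are unioned; a locus absent from
one cohort's call set is imputed homozygous reference for that cohort. This
is a deliberate design choice (the alternative — treating absent loci as
missing — would discard most of the matrix when call sets differ): under
joint capture, absence from a cohort VCF overwhelmingly means "no carrier",
and the shared-presence filter below removes exactly the variants for which
differential callability could masquerade as association. The choice is
recorded in the run's persisted configuration.

## Filtering cascade

Fixed order, with a ledger (`FilterReport`) recording each stage:

1. **Panel regions** — keep variants inside ≥1 panel interval; a variant in
   overlapping genes maps to each of them (it appears once in the matrix
   but contributes to each mapped gene's test).
2. **Shared presence** — keep variants with ≥1 alternative-allele carrier
   in *each* cohort; group-exclusive variants are removed as potential
   calling artifacts.
3. **Exact HWE** — remove variants with exact conditional HWE p < α_HWE.

The ledger identity `n_final = n_after_shared − n_hwe_excluded` is asserted
on every run. Note the conditioning order matters (a group-exclusive
variant never reaches the HWE test); the cascade order is part of the
pipeline's definition.

**HWE test.** Conditional on minor-allele count m among n called diploid
genotypes, the heterozygote count h has
P(h | n, m) = C(n; h, (m−h)/2, n−(m+h)/2)·2^h / C(2n, m) over h with the
parity of m. The two-sided p-value sums P(h) ≤ P(h_obs), the standard exact
formulation, which is well behaved at n ≈ 40 where the χ² approximation is
not. Defaults: α_HWE = 0.05, computed on cases + controls combined; both
are configurable (`hwe_alpha`, `hwe_population`) because reasonable
pipelines differ on the population used. Missing genotypes are dropped per
site (complete-case); sites monomorphic after dropping return p = 1.

## Association tests

All tests are two-sided exact conditional tests with the probability-mass
criterion: the p-value is the total probability of outcomes no more likely
than the observed one under the fixed-margins null.

* **Allele level (2×2):** per group, alt count = Σ dosages over called
  genotypes; ref count = 2·n_called − alt.
* **Genotype level (2×3):** per group, counts of dosage classes 0/1/2.
* **Gene level:** elementwise sums of the per-variant tables over the
  gene's surviving variants — a collapsing burden test. The genotype-level
  pooling mirrors the allele-level pooling (variant × sample observations
  stacked); pooling counts rather than combining per-variant p-values keeps
  the gene test exact and its frequencies interpretable (pooled alt /
  pooled alleles, the quantity reported per group).

Implementation: table probabilities are multivariate hypergeometric,
evaluated with a cached integer log-factorial table; for each margin class
the whole p-value grid is computed at once by sorting outcome probabilities
and cumulating (complexity O(G log G) for a grid of G outcomes), with small
classes memoised. Ties in "no more likely than observed" are accepted up to
a relative tolerance of 1e-7 (the convention R's `fisher.test` uses), so
mathematically tied symmetric outcomes are always included. The unit and
acceptance suites verify both tests against exact rational-arithmetic
enumeration (all HWE triples with total ≤ 50; all 2×2 tables with N ≤ 60;
all 2×3 tables with N ≤ 40) at 1e-10.

**Degenerate tables** (a group with zero called observations, or fewer than
two populated categories after dropping empty columns) carry no information
about association: they get p = 1, are flagged untestable, and are excluded
from the multiplicity family.

**Multiplicity.** Benjamini–Hochberg step-up q-values (via statsmodels),
applied separately within four families: variant-allele, variant-genotype,
gene-allele, gene-genotype. The gene families contain only genes with ≥1
surviving variant (genes with no testable variant have no p-value; family
sizes are reported in the summary JSON). Significance defaults to
FDR < 0.05. A gene counts as significant for replication carry-forward if
*either* family flags it — the union rule mirrors how both allele- and
genotype-driven genes are carried into replication in this design; note the
union of two level-α families is not itself a level-α procedure (each
family individually controls FDR).

## Gene-set burden and trend test

Per-individual burden defaults to **carrier counting** (number of variant
sites with dosage ≥ 1; MISSING contributes 0) because the natural axis for
"variants per individual" counts sites; allele counting (Σ dosages) is an
option. Individuals are binned by burden — default: K = 5 equal-width bins
spanning the observed range (explicit edges configurable; out-of-range
values clamp to the terminal bins with a warning) — and the 2×K
group × bin table is tested for linear trend:

χ² = N·r², where r is the Pearson correlation between the group indicator
and the column score across the N individuals, referred to χ²(1 df).
Default scores are bin midpoints, which approximates a trend test on the
underlying counts while operating on the binned table; integer ranks or
explicit scores are options. The statistic is invariant to affine score
changes. Degenerate tables (one group, or a single occupied bin) return
p = 1 flagged. A Wilcoxon rank-sum test on the raw unbinned burdens is
reported alongside as a sensitivity check; the binned trend test is the
headline statistic.

## Replication stage

Candidate genes = discovery genes with q < α in either family; candidate
variants = their surviving variants; panel-present = candidates with ≥1
panel individual carrying the alternative allele. The case cohort is
compared against the panel with the identical pooled-table machinery over
panel-present variants only; BH runs inside the candidate-gene family (the
replication question is confirmatory, posed only for the candidates). A
gene losing all its variants to panel absence is dropped with a log entry.
Two structural properties are enforced by tests: replication depends only
on panel-present variants, and replicating against the discovery control
cohort reproduces the discovery gene-level p-values exactly.

## Synthetic cohorts

The simulator emulates the statistical structure the analysis assumes, at
the design's scale — defaults: 13 cases, 27 controls, 107 panel samples,
50 genes × 40 SNVs (autosomes, non-overlapping intervals), per-variant base
allele frequency uniform on [0.05, 0.5], 2% genotype missingness in the
sequenced cohorts (panel calls stay complete, as reference-set genotypes
do). Genotypes are binomial(2, f) per individual (HWE). Injected structure,
all recorded in a ground-truth object:

* **effect genes** — an absolute case-cohort allele frequency per gene
  (controls and panel keep the base frequency), e.g. control 0.2 vs case
  0.4 in the power scenario;
* **HWE violators** — genotypes drawn from the inbreeding-parameterised law
  (hom-ref (1−f)² + F·f(1−f); het 2f(1−f)(1−F); hom-alt f² + F·f(1−f)),
  one scalar F ∈ (−1, 1) controlling the departure (default 0.8);
* **group-exclusive variants** — carriers forced into one cohort only
  (a carrier is guaranteed), frequency 0.3;
* **burden shift** — the case allele frequency of non-effect variants is
  multiplied by a factor (default 1.0; the power scenario uses 1.25, a
  modest per-variant inflation producing a clearly detectable gene-set
  shift at 200 vs 200);
* **panel absences** — variants forced absent from the panel, so
  replication sets genuinely lose candidates.

Each cohort's VCF contains only the variants with ≥1 called carrier in that
cohort, mirroring per-cohort caller output; the panel VCF is written with
phased separators as reference panels are. Everything is a pure function of
the seed, and the emitted VCF headers carry no timestamps, so identical
configs give byte-identical files.

**What the simulator does not model** — and hence what passing tests do not
establish about real data: linkage disequilibrium between variants (real
burden counts have correlated components; the trend test's null calibration
holds under independence), haplotype phase, sequencing error or genotype
uncertainty, indels and multi-allelic sites (the readers handle them; the
simulator emits biallelic SNVs), population stratification, and relatedness.

## Calibration facts worth knowing

* With 13 vs 27 samples the exact tests are discrete and conservative: the
  attainable size of the variant-level allele test at nominal 0.05 is about
  0.03. This is a property of exact conditional tests at small n, not a
  defect; it is why the null-calibration check bounds the rejection rate
  above by the nominal level rather than demanding equality.
* Under a global null, BH makes ≥1 gene-level discovery in ≈α of runs per
  family (Simes equality); the union over the allele and genotype families
  exceeds α slightly. FDR control is a per-family statement.
* With strong injected effects, BH at 5% lets one null gene ride along in
  roughly a tenth of replicates (a false-discovery *proportion* of ~1/3 in
  those runs is consistent with FDR ≤ 5%); per-gene false-flag rates stay
  near zero.

## Numerical and edge-case choices

* Probability sums run in ascending order (sorted cumulative sums), keeping
  enumeration error near machine precision even for 10⁶-outcome grids.
* p-values are clamped into (0, 1]; the trend p is floored at the smallest
  positive double rather than returning 0.
* Burden binning with all-identical burdens widens to a unit-width bin and
  the trend test reports a degenerate p = 1.
* Variants with duplicate keys within one VCF are an error (they would
  break pooling identities silently).
* The bundled 457-gene panel BED is a synthetic placeholder (generic
  symbols, evenly spaced intervals) sized like a curated skeletal gene set;
  it exists so the end-to-end tooling runs out of the box and must be
  replaced by a real curated panel for any substantive analysis.

## Problem sizes used by the test and acceptance runs

Oracle sweeps: all HWE genotype triples with total ≤ 50; all 2×2 tables
with N ≤ 60; all 2×3 tables with N ≤ 40 (9.4M tables, checked per margin
class against independent enumeration). Calibration: 200 null replicates at
13 vs 27 with 2000 variants over 50 genes; 100 power replicates at
200 vs 200 with 2 effect genes (f 0.2 → 0.4, 5 variants/gene); 500 null
replicates for trend-p uniformity; the acceptance script uses 60 null and
40 power replicates. These sizes give binomial standard errors comfortably
inside the asserted margins while keeping a full run in a few minutes on
one CPU.
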