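import numpy as np
import pytest

from geneburden import GenePanel, GenotypeMatrix, MISSING, VariantKey
from geneburden.simulate import SimulationConfig, simulate


def make_matrix(dosages, groups_per_sample, chrom="1", start_pos=1000, prefix="S"):
    """Small handcrafted GenotypeMatrix; one variant per dosage row."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_var, n_samp = dosages.shape
    variants = [VariantKey(chrom, start_pos + 10 * i, "A", "G") for i in range(n_var)]
    samples = [f"{prefix}{j}" for j in range(n_samp)]
    return GenotypeMatrix(
        variants=variants,
        samples=samples,
        groups={s: g for s, g in zip(samples, groups_per_sample)},
        dosages=dosages,
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study reused by read-only tests."""
    cfg = SimulationConfig(
        seed=42,
        n_genes=8,
        variants_per_gene=15,
        n_hwe_violators=6,
        n_group_exclusive=3,
        effect_genes={"G001": 0.45},
        freq_overrides={"G001": 0.2},
        missing_rate=0.03,
    )
    return simulate(cfg)


@pytest.fixture()
def two_group_matrix():
    """3 variants x 6 samples, AFF x3 / OP x3, with one missing call."""
    return make_matrix(
        [
            [0, 1, 2, 0, 0, 1],
            [1, 0, 0, 1, MISSING, 0],
            [2, 2, 1, 0, 1, 1],
        ],
        ["AFF", "AFF", "AFF", "OP", "OP", "OP"],
    )


@pytest.fixture()
def simple_panel():
    return GenePanel.from_intervals(
        [
            ("1", 900, 1100, "GENEA"),
            ("1", 1000, 1200, "GENEB"),
            ("2", 0, 500, "GENEC"),
        ]
    )
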