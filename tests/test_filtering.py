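import numpy as np
import pytest

from geneburden import (
    GenePanel,
    MISSING,
    UsageError,
    VariantKey,
    apply_filter_cascade,
    filter_by_regions,
    hwe_exact_pvalue,
    hwe_filter,
    shared_presence_filter,
)
from geneburden.core import GenotypeMatrix
from geneburden.filtering import FilterReport, genotype_counts
from geneburden.simulate import SimulationConfig, simulate

from conftest import make_matrix


def matrix_at_positions(positions, chrom="1", n_samples=4, group="AFF"):
    samples = [f"S{j}" for j in range(n_samples)]
    dos = np.ones((len(positions), n_samples), dtype=np.int8)
    return GenotypeMatrix(
        variants=[VariantKey(chrom, p, "A", "G") for p in positions],
        samples=samples,
        groups={s: group for s in samples},
        dosages=dos,
    )


class TestGenotypeCounts:
    def test_tally_ignores_missing(self):
        assert genotype_counts(np.array([0, 1, 2, 2, MISSING])) == (1, 1, 2)


class TestRegionFilter:
    def test_containment_and_assignment(self, simple_panel):
        # GENEA spans 1-based 901..1100; GENEB 1001..1200; both overlap 1001..1100
        gm = matrix_at_positions([950, 1050, 1150, 1300])
        kept, assign = filter_by_regions(gm, simple_panel)
        assert [v.pos for v in kept.variants] == [950, 1050, 1150]
        assert assign[VariantKey("1", 950, "A", "G")] == ["GENEA"]
        assert assign[VariantKey("1", 1050, "A", "G")] == ["GENEA", "GENEB"]
        assert assign[VariantKey("1", 1150, "A", "G")] == ["GENEB"]

    def test_half_open_boundaries(self):
        # interval (100, 250) covers 1-based positions 101..250 inclusive
        panel = GenePanel.from_intervals([("1", 100, 250, "G")])
        gm = matrix_at_positions([100, 101, 250, 251])
        kept, _ = filter_by_regions(gm, panel)
        assert [v.pos for v in kept.variants] == [101, 250]

    def test_counts_match_brute_force_scan(self):
        rng = np.random.default_rng(3)
        panel = GenePanel.from_intervals(
            [("1", 1000, 2000, "G1"), ("1", 5000, 5500, "G2"), ("2", 0, 800, "G3")]
        )
        pos = sorted(set(rng.integers(1, 7000, size=100).tolist()))
        gm = matrix_at_positions(pos)
        kept, assign = filter_by_regions(gm, panel)
        expected = [
            p for p in pos
            if 1000 <= p - 1 < 2000 or 5000 <= p - 1 < 5500
        ]
        assert [v.pos for v in kept.variants] == expected
        assert set(assign) == set(kept.variants)

    def test_empty_result_allowed(self, simple_panel):
        gm = matrix_at_positions([5000])
        kept, assign = filter_by_regions(gm, simple_panel)
        assert kept.n_variants == 0 and assign == {}


class TestSharedPresence:
    def test_rule(self):
        gm = make_matrix(
            [
                [1, 1, 0, 0],  # AFF-exclusive -> dropped
                [0, 1, 1, 0],  # one het in each group -> kept
                [0, 0, 0, 2],  # OP-exclusive -> dropped
                [0, MISSING, 1, 1],  # carriers in OP only -> dropped
            ],
            ["AFF", "AFF", "OP", "OP"],
        )
        kept, excluded = shared_presence_filter(gm, ("AFF", "OP"))
        assert [v.pos for v in kept.variants] == [1010]
        assert len(excluded) == 3

    def test_absent_group_rejected(self, two_group_matrix):
        with pytest.raises(UsageError):
            shared_presence_filter(two_group_matrix, ("AFF", "nope"))

    def test_injected_exclusives_recovered_exactly(self):
        # high base frequencies make chance exclusives vanishingly unlikely
        cfg = SimulationConfig(
            seed=5, n_genes=6, variants_per_gene=12, n_group_exclusive=4,
            base_freq_range=(0.3, 0.5), missing_rate=0.0,
        )
        study = simulate(cfg)
        injected = {
            k for ks in study.truth.group_exclusive_keys.values() for k in ks
        }
        _, excluded = shared_presence_filter(study.joined(), ("AFF", "OP"))
        assert set(excluded) == injected


class TestHweFilter:
    def test_excess_homozygote_variant_removed(self):
        gm = make_matrix(
            [[2, 2, 2, 0, 0, 0, 0, 2, 2, 0], [1, 0, 1, 0, 1, 0, 1, 0, 1, 0]],
            ["AFF"] * 5 + ["OP"] * 5,
        )
        assert hwe_exact_pvalue(5, 0, 5) < 0.05
        kept, excluded = hwe_filter(gm, alpha=0.05)
        assert [v.pos for v in kept.variants] == [1010]
        assert excluded[0][0].pos == 1000 and excluded[0][1] < 0.05

    def test_monomorphic_after_missing_retained(self):
        gm = make_matrix([[0, 0, MISSING, MISSING]], ["AFF", "AFF", "OP", "OP"])
        kept, excluded = hwe_filter(gm, alpha=0.05)
        assert kept.n_variants == 1 and excluded == []

    def test_tiny_alpha_excludes_nothing(self, small_study):
        gm = small_study.joined()
        kept, excluded = hwe_filter(gm, alpha=1e-300)
        assert kept.n_variants == gm.n_variants and excluded == []

    def test_population_selector(self):
        # AFF genotypes wildly out of HWE, OP in HWE
        gm = make_matrix(
            [[2, 2, 0, 0, 1, 0, 1, 1, 0, 1, 0, 0, 1, 0]],
            ["AFF"] * 4 + ["OP"] * 10,
        )
        _, excl_all = hwe_filter(gm, alpha=0.05, population="OP")
        assert excl_all == []

    def test_bad_arguments(self, two_group_matrix):
        with pytest.raises(UsageError):
            hwe_filter(two_group_matrix, alpha=0.0)
        with pytest.raises(UsageError):
            hwe_filter(two_group_matrix, population="nope")

    def test_null_exclusion_rate_bounded_by_alpha(self):
        # HWE-true genotypes: exclusion fraction ~ attainable size <= alpha
        rng = np.random.default_rng(23)
        n, m = 400, 1500
        dos = rng.binomial(2, 0.3, size=(m, n)).astype(np.int8)
        gm = GenotypeMatrix(
            variants=[VariantKey("1", 100 + i, "A", "G") for i in range(m)],
            samples=[f"S{j}" for j in range(n)],
            groups={f"S{j}": "OP" for j in range(n)},
            dosages=dos,
        )
        _, excluded = hwe_filter(gm, alpha=0.05)
        rate = len(excluded) / m
        se = (0.05 * 0.95 / m) ** 0.5
        assert rate <= 0.05 + 3 * se


class TestCascade:
    def test_ledger_identity_and_stage_order(self, small_study):
        gm = small_study.joined()
        final, assign, report = apply_filter_cascade(gm, small_study.panel, ("AFF", "OP"))
        report.validate()
        assert report.n_input == gm.n_variants
        assert report.n_final == final.n_variants
        assert report.n_final == report.n_after_shared - report.n_hwe_excluded
        stages = [s for _, s, _ in report.excluded]
        # stage blocks appear in cascade order
        assert stages == sorted(stages, key=["region", "shared", "hwe"].index)
        assert set(assign) == set(final.variants)

    def test_report_validation_catches_inconsistency(self):
        bad = FilterReport(n_input=10, n_after_region=10, n_after_shared=8,
                           n_hwe_excluded=1, n_final=6)
        with pytest.raises(AssertionError):
            bad.validate()

    def test_report_serialization(self, tmp_path, small_study):
        _, _, report = apply_filter_cascade(
            small_study.joined(), small_study.panel, ("AFF", "OP")
        )
        report.to_json(tmp_path / "r.json")
        report.write_excluded_tsv(tmp_path / "r.tsv")
        import json

        d = json.loads((tmp_path / "r.json").read_text())
        assert d["n_final"] == d["n_after_shared"] - d["n_hwe_excluded"]
        assert (tmp_path / "r.tsv").read_text().startswith("variant\tstage\treason")
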