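import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geneburden import (
    MISSING,
    UsageError,
    VariantKey,
    allele_table,
    bh_fdr,
    gene_pooled_tables,
    genotype_table,
    run_gene_level,
    run_variant_level,
)

from conftest import make_matrix
from oracles import bh_stepup_reference

GROUPS = ("AFF", "OP")


def tally_oracle(dosages, group_cols):
    """Naive per-sample tally of allele and genotype counts for one variant."""
    allele, geno = [], []
    for cols in group_cols:
        called = [d for d in dosages[cols] if d != MISSING]
        alt = sum(called)
        allele.append([alt, 2 * len(called) - alt])
        geno.append([sum(d == k for d in called) for k in (0, 1, 2)])
    return np.array(allele), np.array(geno)


class TestTables:
    def test_allele_counting_rule(self):
        gm = make_matrix([[1, 2, 0, 0, 0, MISSING]], ["AFF"] * 3 + ["OP"] * 3)
        at = allele_table(gm, gm.variants[0], GROUPS)
        assert at.counts.tolist() == [[3, 3], [0, 4]]

    def test_genotype_counting_rule(self):
        gm = make_matrix([[1, 2, 0, 0, 0, MISSING]], ["AFF"] * 3 + ["OP"] * 3)
        gt = genotype_table(gm, gm.variants[0], GROUPS)
        assert gt.counts.tolist() == [[1, 1, 1], [2, 0, 0]]

    def test_all_missing_group_flagged_degenerate(self):
        gm = make_matrix([[1, 1, MISSING, MISSING]], ["AFF", "AFF", "OP", "OP"])
        at = allele_table(gm, gm.variants[0], GROUPS)
        assert at.counts[1].tolist() == [0, 0]
        assert at.degenerate

    def test_absent_variant_raises(self, two_group_matrix):
        with pytest.raises(KeyError):
            allele_table(two_group_matrix, VariantKey("9", 1, "A", "G"), GROUPS)

    def test_random_matrices_match_tally_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            dos = rng.choice([0, 1, 2, MISSING], size=(5, 12), p=[0.5, 0.25, 0.15, 0.1])
            gm = make_matrix(dos, ["AFF"] * 5 + ["OP"] * 7)
            cols = [np.arange(5), np.arange(5, 12)]
            for i, v in enumerate(gm.variants):
                exp_a, exp_g = tally_oracle(dos[i], cols)
                assert np.array_equal(allele_table(gm, v, GROUPS).counts, exp_a)
                assert np.array_equal(genotype_table(gm, v, GROUPS).counts, exp_g)


class TestGenePooling:
    def test_additivity_of_identical_variants(self):
        gm = make_matrix(
            [[1, 2, 0, 0, 0, 0], [1, 2, 0, 0, 0, 0]], ["AFF"] * 3 + ["OP"] * 3
        )
        assign = {v: ["G"] for v in gm.variants}
        at, gt, n = gene_pooled_tables(gm, "G", assign, GROUPS)
        single = allele_table(gm, gm.variants[0], GROUPS)
        assert n == 2
        assert np.array_equal(at.counts, 2 * single.counts)
        assert at.counts[0, 0] / at.counts[0].sum() == pytest.approx(0.5)

    def test_single_variant_gene_is_identity(self, two_group_matrix):
        gm = two_group_matrix
        assign = {gm.variants[0]: ["G"]}
        at, gt, n = gene_pooled_tables(gm, "G", assign, GROUPS)
        assert n == 1
        assert np.array_equal(at.counts, allele_table(gm, gm.variants[0], GROUPS).counts)
        assert np.array_equal(gt.counts, genotype_table(gm, gm.variants[0], GROUPS).counts)

    def test_pool_matches_concatenated_tally(self):
        rng = np.random.default_rng(37)
        dos = rng.choice([0, 1, 2, MISSING], size=(6, 10), p=[0.4, 0.3, 0.2, 0.1])
        gm = make_matrix(dos, ["AFF"] * 4 + ["OP"] * 6)
        assign = {v: ["G"] for v in gm.variants}
        at, gt, _ = gene_pooled_tables(gm, "G", assign, GROUPS)
        cols = [np.arange(4), np.arange(4, 10)]
        exp_a = sum(tally_oracle(dos[i], cols)[0] for i in range(6))
        exp_g = sum(tally_oracle(dos[i], cols)[1] for i in range(6))
        assert np.array_equal(at.counts, exp_a)
        assert np.array_equal(gt.counts, exp_g)

    def test_gene_without_variants_rejected(self, two_group_matrix):
        with pytest.raises(UsageError):
            gene_pooled_tables(two_group_matrix, "G", {}, GROUPS)


class TestBhFdr:
    def test_singleton_identity(self):
        assert bh_fdr([0.05]).tolist() == [0.05]

    def test_stepup_hand_example(self):
        # min over i>=k of p_(i) * m / i: all collapse to 0.04
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_empty(self):
        assert bh_fdr([]).size == 0

    def test_invalid_pvalues(self):
        with pytest.raises(UsageError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(UsageError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0, exclude_min=False),
                 min_size=1, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_textbook_stepup(self, ps):
        q = bh_fdr(ps)
        np.testing.assert_allclose(q, bh_stepup_reference(ps), rtol=1e-12, atol=0)
        assert (q >= np.asarray(ps) - 1e-15).all()
        assert (q <= 1.0).all()
        # monotone: sorted q respects sorted p order
        order = np.argsort(ps)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(41)
        p = rng.uniform(1e-6, 1, size=30)
        perm = rng.permutation(30)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]), rtol=1e-12)


class TestRunners:
    def test_single_variant_q_equals_p(self):
        gm = make_matrix([[1, 2, 0, 1, 0, 0]], ["AFF"] * 3 + ["OP"] * 3)
        res = run_variant_level(gm, GROUPS)
        assert len(res) == 1
        assert res[0].q_allele == pytest.approx(res[0].p_allele)
        assert res[0].q_genotype == pytest.approx(res[0].p_genotype)

    def test_degenerate_variants_leave_bh_family(self):
        gm = make_matrix(
            [
                [1, 2, 0, 1, 0, 0],
                [1, 1, 1, MISSING, MISSING, MISSING],  # OP all missing
                [0, 1, 0, 1, 1, 0],
            ],
            ["AFF"] * 3 + ["OP"] * 3,
        )
        res = run_variant_level(gm, GROUPS)
        flags = [r.testable_allele for r in res]
        assert flags == [True, False, True]
        # untestable result carries p=1-style placeholder q of 1
        assert res[1].q_allele == 1.0
        # BH family of size 2: q = min over the two testable entries
        testable_p = [res[0].p_allele, res[2].p_allele]
        expected_q = bh_stepup_reference(testable_p)
        assert res[0].q_allele == pytest.approx(expected_q[0])
        assert res[2].q_allele == pytest.approx(expected_q[1])

    def test_single_gene_q_equals_p(self, two_group_matrix):
        gm = two_group_matrix
        assign = {v: ["G"] for v in gm.variants}
        res = run_gene_level(gm, assign, GROUPS)
        assert len(res) == 1
        assert res[0].q_allele == pytest.approx(res[0].p_allele)
        assert res[0].n_variants == 3

    def test_gene_frequencies_match_arithmetic(self):
        gm = make_matrix(
            [[1, 2, 0, 0, 0, 0], [2, 2, 2, 1, 0, 0]], ["AFF"] * 3 + ["OP"] * 3
        )
        assign = {gm.variants[0]: ["G1"], gm.variants[1]: ["G1", "G2"]}
        res = {r.unit: r for r in run_gene_level(gm, assign, GROUPS)}
        # G1 pools both variants: AFF alt = 3 + 6 = 9 of 12; OP alt = 0 + 1 of 12
        assert res["G1"].freq_by_group["AFF"] == pytest.approx(9 / 12)
        assert res["G1"].freq_by_group["OP"] == pytest.approx(1 / 12)
        # G2 only the second variant
        assert res["G2"].freq_by_group["AFF"] == pytest.approx(1.0)
        assert res["G2"].n_variants == 1

    def test_multi_gene_variant_counted_in_both(self):
        gm = make_matrix([[1, 1, 0, 1, 0, 0]], ["AFF"] * 3 + ["OP"] * 3)
        assign = {gm.variants[0]: ["G1", "G2"]}
        res = run_gene_level(gm, assign, GROUPS)
        assert sorted(str(r.unit) for r in res) == ["G1", "G2"]
        assert res[0].p_allele == res[1].p_allele
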