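"""Fisher's method, quadrant assignment, exact 2x2 tests, coupling rho."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from synaptomics import (assign_quadrants, coupling_correlation, fisher_combine,
                         fisher_exact_2x2, match_omics, quadrant_association_test,
                         select_significant)
from synaptomics.integration import OmicsIntegration, quadrant_counts


class TestFisherCombine:
    def test_all_ones_combine_to_one(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)

    def test_single_p_is_identity(self):
        for p in (0.3, 0.05, 0.999, 1e-8):
            assert fisher_combine([p]) == pytest.approx(p, rel=1e-9)

    def test_two_equal_ps_against_chi2_oracle(self):
        x = -2 * (math.log(0.05) + math.log(0.05))
        assert x == pytest.approx(11.9829, abs=1e-4)
        assert fisher_combine([0.05, 0.05]) == pytest.approx(stats.chi2.sf(x, 4), rel=1e-12)

    def test_rejects_zero_and_empty(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])
        with pytest.raises(ValueError):
            fisher_combine([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=5),
           st.integers(min_value=0, max_value=4), st.floats(min_value=0.1, max_value=0.9))
    def test_monotone_in_every_input(self, pvals, idx, factor):
        """Decreasing any input p never increases the combined p."""
        idx = idx % len(pvals)
        smaller = list(pvals)
        smaller[idx] *= factor
        assert fisher_combine(smaller) <= fisher_combine(pvals) + 1e-12


def enumerate_two_sided(a, b, c, d):
    """Exact-integer hypergeometric enumeration (independent oracle)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    masses = [math.comb(r1, x) * math.comb(n - r1, c1 - x) for x in range(lo, hi + 1)]
    obs = masses[a - lo]
    return sum(m for m in masses if m <= obs) / math.comb(n, c1)


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ([[1, 1], [1, 1]], 1.0),
        ([[2, 0], [0, 2]], 1 / 3),
        ([[10, 10], [10, 10]], 1.0),
    ])
    def test_small_tables_by_enumeration(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-9)

    def test_printed_overlap_table_is_extreme(self):
        assert fisher_exact_2x2([[60, 498], [261, 344]]) < 1e-6

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    def test_agrees_with_enumeration_and_scipy(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_2x2([[a, b], [c, d]])
        assert p == pytest.approx(enumerate_two_sided(a, b, c, d), rel=1e-8)
        assert p == pytest.approx(stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-6)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [1, 1]])


class TestQuadrants:
    @pytest.mark.parametrize("rna,prot,expected", [
        (1.0, 2.0, "Q1"), (1.0, -1.0, "Q2"), (-1.0, -1.0, "Q3"),
        (-1.0, 1.0, "Q4"), (0.0, 1.0, "boundary"), (1.0, 0.0, "boundary"),
    ])
    def test_sign_pairs(self, rna, prot, expected):
        assert assign_quadrants(rna, prot) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            assign_quadrants(np.nan, 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(-5, 5)), min_size=1,
                    max_size=50))
    def test_quadrant_counts_conserve_genes(self, pairs):
        matched = pd.DataFrame(pairs, columns=["rna_log2fc", "prot_log2fc"])
        matched["quadrant"] = assign_quadrants(matched["rna_log2fc"].to_numpy(),
                                               matched["prot_log2fc"].to_numpy())
        assert quadrant_counts(matched).sum() == len(matched)


def fake_matched(q1, q2, q3, q4):
    rows = ([(1, 1)] * q1 + [(1, -1)] * q2 + [(-1, -1)] * q3 + [(-1, 1)] * q4)
    df = pd.DataFrame(rows, columns=["rna_log2fc", "prot_log2fc"])
    df["quadrant"] = assign_quadrants(df["rna_log2fc"].to_numpy(),
                                      df["prot_log2fc"].to_numpy())
    return df


class TestQuadrantAssociation:
    def test_balanced_table_is_independent(self):
        assert quadrant_association_test(fake_matched(10, 10, 10, 10)) == pytest.approx(1.0)
        assert quadrant_association_test(fake_matched(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_diagonal_concentration_is_extreme(self):
        # all genes on the Q1/Q3 diagonal: signs perfectly associated
        p = quadrant_association_test(fake_matched(50, 0, 50, 0))
        assert p < 1e-20
        assert p == pytest.approx(enumerate_two_sided(50, 0, 0, 50), rel=1e-6)
        # all mass in one column is a degenerate margin: p = 1
        assert quadrant_association_test(fake_matched(50, 0, 0, 50)) == 1.0

    def test_all_boundary_rejected(self):
        df = pd.DataFrame({"rna_log2fc": [0.0], "prot_log2fc": [1.0]})
        df["quadrant"] = ["boundary"]
        with pytest.raises(ValueError):
            quadrant_association_test(df)


def diff_table(entries):
    df = pd.DataFrame(entries, columns=["gene_id", "log2fc", "p", "padj"]).set_index("gene_id")
    return df


class TestMatchOmics:
    def test_join_semantics(self):
        rna = diff_table([(f"G{i}", 1.0, 0.5, 0.5) for i in range(5)])
        prot = diff_table([(f"G{i}", -1.0, 0.5, 0.5) for i in range(2, 5)])
        matched = match_omics(rna, prot)
        assert len(matched) == 3
        assert set(matched["quadrant"]) == {"Q2"}

    def test_disjoint_tables_give_empty(self):
        matched = match_omics(diff_table([("A", 1, 0.1, 0.1)]),
                              diff_table([("B", 1, 0.1, 0.1)]))
        assert len(matched) == 0

    def test_combined_p_recomputed_per_row(self):
        rna = diff_table([("G1", 1, 0.01, 0.02), ("G2", 1, 0.5, 0.6)])
        prot = diff_table([("G1", 1, 0.05, 0.07), ("G2", 1, 0.9, 0.95)])
        matched = match_omics(rna, prot)
        for g in ("G1", "G2"):
            expect = fisher_combine([rna.loc[g, "padj"], prot.loc[g, "padj"]])
            assert matched.loc[g, "combined_p"] == pytest.approx(expect, rel=1e-12)

    def test_raw_p_combination_flag(self):
        rna = diff_table([("G1", 1, 0.01, 0.5)])
        prot = diff_table([("G1", 1, 0.01, 0.5)])
        raw = match_omics(rna, prot, combine_on="p")
        adj = match_omics(rna, prot, combine_on="padj")
        assert raw.loc["G1", "combined_p"] < adj.loc["G1", "combined_p"]

    def test_duplicate_gene_rejected(self):
        dup = pd.concat([diff_table([("G1", 1, 0.1, 0.1)])] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            match_omics(dup, diff_table([("G1", 1, 0.1, 0.1)]))


class TestSelectSignificant:
    def setup_method(self):
        rna = diff_table([("A", 1, 0.001, 0.01), ("B", 1, 0.001, 0.01),
                          ("C", 1, 0.5, 0.9)])
        prot = diff_table([("A", 1, 0.001, 0.01), ("B", 1, 0.3, 0.6),
                           ("C", 1, 0.5, 0.9)])
        self.matched = match_omics(rna, prot)

    def test_intersection_stricter_than_fisher(self):
        fisher = select_significant(self.matched, 0.05, "fisher")
        inter = select_significant(self.matched, 0.05, "intersection")
        assert set(inter.index) <= set(fisher.index)
        assert "B" not in inter.index  # prot_padj 0.6 fails the intersection

    def test_alpha_one_keeps_everything(self):
        assert len(select_significant(self.matched, 1.0, "fisher")) == 3
        assert len(select_significant(self.matched, 1.0, "intersection")) == 3

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            select_significant(self.matched, 0.05, "bonferroni")


class TestCouplingCorrelation:
    def test_monotone_relationships(self):
        x = np.array([0.1, 0.5, 1.2, 3.0, 5.5])
        assert coupling_correlation(x, np.exp(x))[0] == pytest.approx(1.0)
        assert coupling_correlation(x, -(x ** 3))[0] == pytest.approx(-1.0)

    def test_hand_rank_example(self):
        rho, _ = coupling_correlation([1, 2, 3, 4], [2, 1, 4, 3])
        assert rho == pytest.approx(0.6, rel=1e-12)  # 1 - 6*4/(4*15)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r0 = coupling_correlation(x, y)[0]
        assert coupling_correlation(np.exp(x), y)[0] == pytest.approx(r0)
        assert coupling_correlation(x, 5 * y + 2)[0] == pytest.approx(r0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            coupling_correlation([1, 2], [3, 4])
        with pytest.raises(ValueError):
            coupling_correlation([1, 1, 1], [1, 2, 3])


class TestIntegrationModel:
    def test_fit_on_simulated_adult_contrast(self, study):
        from synaptomics.abundance import DifferentialExpression
        diffs = {}
        for layer in ("rna", "protein"):
            diffs[layer] = DifferentialExpression(
                study.layer(layer),
                group_a={"compartment": "TH", "age_group": "5m"},
                group_b={"compartment": "SYN", "age_group": "5m"}).fit()
        res = OmicsIntegration(diffs["rna"], diffs["protein"], "SYN vs TH (5m)").fit()
        assert len(res.matched) == study.matrix("protein", "TH").n_genes
        assert res.quadrant_counts.sum() == len(res.matched)
        # programmed anti-diagonal classes make the sign table non-uniform
        assert res.association_p < 0.05
        assert "quadrant counts" in res.summary()
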