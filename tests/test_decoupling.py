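"""Decoupling scores, age trends, RNA-protein coupling, two-way ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from synaptomics import (decoupling_score, decoupling_table,
                         per_gene_age_correlation, rna_protein_coupling,
                         two_way_anova)
from synaptomics.decoupling import coupling_anova

from conftest import make_matrix


class TestDecouplingScore:
    @pytest.mark.parametrize("prot,rna,expected", [
        (1.0, 1.0, 0.0),     # perfectly coupled
        (2.0, 1.0, 1.0),     # protein increases more -> positive
        (-2.0, -1.0, -1.0),  # protein decreases more -> negative
        (0.5, -0.5, 1.0),    # protein up while transcript down
    ])
    def test_sign_semantics(self, prot, rna, expected):
        assert decoupling_score(prot, rna) == expected

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            decoupling_score(np.nan, 1.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_self_coupling_zero_and_antisymmetry(self, x, y):
        assert decoupling_score(x, x) == 0.0
        assert decoupling_score(x, y) == -decoupling_score(y, x)

    def test_table_join_and_exact_identity(self):
        rna = pd.DataFrame({"log2fc": [1.0, -1.0]}, index=["G1", "G2"])
        prot = pd.DataFrame({"log2fc": [2.0, 0.5]}, index=["G1", "G3"])
        tab = decoupling_table(rna, prot, "SYN aging")
        assert list(tab.index) == ["G1"]
        assert tab.loc["G1", "decoupling"] == tab.loc["G1", "prot_log2fc"] - \
            tab.loc["G1", "rna_log2fc"]


class TestPerGeneAgeCorrelation:
    def age_matrix(self, rows, lengths=None):
        ages = ["3w", "3w", "5m", "5m", "18m", "18m"]
        return make_matrix(rows, layer="protein", ages=ages)

    def test_strictly_increasing_gene_is_maximally_correlated(self):
        # with replicate-tied age ranks the maximum attainable |rho| is the
        # value Spearman assigns to a perfectly monotone gene
        m = self.age_matrix({"G1": [1, 2, 3, 4, 5, 6], "G2": [6, 5, 4, 3, 2, 1]})
        rho = per_gene_age_correlation(m, "intensity")
        ages = m.meta["age_numeric"]
        expect = stats.spearmanr([1, 2, 3, 4, 5, 6], ages).statistic
        assert rho["G1"] == pytest.approx(expect)
        assert rho["G2"] == pytest.approx(-expect)
        assert rho["G1"] > 0.9

    def test_invariant_to_age_encoding(self):
        m1 = self.age_matrix({"G1": [1, 3, 2, 5, 4, 8]})
        m2 = self.age_matrix({"G1": [1, 3, 2, 5, 4, 8]})
        m2.meta["age_numeric"] = [1, 1, 2, 2, 3, 3]
        r1 = per_gene_age_correlation(m1, "intensity")
        r2 = per_gene_age_correlation(m2, "intensity")
        assert r1["G1"] == pytest.approx(r2["G1"])

    def test_constant_gene_emits_nan_with_warning(self):
        m = self.age_matrix({"G1": [2, 2, 2, 2, 2, 2], "G2": [1, 2, 3, 4, 5, 6]})
        with pytest.warns(UserWarning, match="constant"):
            rho = per_gene_age_correlation(m, "intensity")
        assert np.isnan(rho["G1"]) and rho["G2"] > 0.9

    def test_single_age_rejected(self):
        m = make_matrix({"G1": [1, 2, 3]}, layer="protein", age_group="5m")
        with pytest.raises(ValueError, match="distinct ages"):
            per_gene_age_correlation(m, "intensity")

    def test_matches_scipy_spearman_per_gene(self, study):
        prot = study.matrix("protein", "SYN")
        rho = per_gene_age_correlation(prot, "intensity")
        ages = prot.meta["age_numeric"].to_numpy()
        for g in prot.genes[:20]:
            expect = stats.spearmanr(prot.values.loc[g], ages).statistic
            assert rho[g] == pytest.approx(expect, rel=1e-9)


class TestRnaProteinCoupling:
    def test_monotone_protein_gives_unit_rho(self, study):
        rna = study.matrix("rna", "TH")
        rpkms = __import__("synaptomics").rpkm(rna)
        prot_values = (rpkms + 1.0) ** 1.7  # per-sample monotone transform
        prot_values.columns = [c.replace("rna", "protein") for c in rpkms.columns]
        meta = rna.meta.copy()
        meta.index = prot_values.columns
        prot = type(rna)(prot_values, meta, "protein")
        series = rna_protein_coupling(rna, prot)
        assert np.allclose(series["rho"], 1.0)

    def test_shuffled_protein_decorrelates(self, study):
        rna = study.matrix("rna", "TH")
        prot = study.matrix("protein", "TH")
        rng = np.random.default_rng(3)
        shuffled = prot.values.sample(frac=1.0, random_state=12)
        shuffled.index = prot.values.index
        prot2 = type(prot)(shuffled, prot.meta, "protein")
        series = rna_protein_coupling(rna, prot2)
        assert series["rho"].abs().max() < 0.08

    def test_compartment_and_age_structure_on_defaults(self, study):
        """Coupling is higher in the soma-dominated total homogenate than in
        synaptosomes, mirroring the soma-driven synthesis of the generator."""
        series = rna_protein_coupling(study.layer("rna"), study.layer("protein"))
        means = series.groupby("compartment")["rho"].mean()
        assert means["TH"] > means["SYN"]
        th = series[series["compartment"] == "TH"].groupby("age_group")["rho"].mean()
        assert th["3w"] > th["18m"]  # aging decouples the soma too
        anova = coupling_anova(series)
        assert anova.p("A") < 0.01  # compartment effect

    def test_no_shared_genes_rejected(self, study):
        rna = study.matrix("rna", "TH")
        prot = study.matrix("protein", "TH")
        renamed = prot.values.copy()
        renamed.index = [f"x_{g}" for g in renamed.index]
        prot2 = type(prot)(renamed, prot.meta, "protein")
        with pytest.raises(ValueError, match="shared genes"):
            rna_protein_coupling(rna, prot2)


def hand_anova_2x3(values, a, b):
    """Balanced two-way ANOVA sums of squares computed from the textbook
    decomposition (independent oracle)."""
    df = pd.DataFrame({"y": values, "a": a, "b": b})
    grand = df["y"].mean()
    n = len(df)
    A, B = df["a"].nunique(), df["b"].nunique()
    r = n / (A * B)
    ss_a = sum(r * B * (df[df["a"] == l]["y"].mean() - grand) ** 2 for l in df["a"].unique())
    ss_b = sum(r * A * (df[df["b"] == l]["y"].mean() - grand) ** 2 for l in df["b"].unique())
    cell_means = df.groupby(["a", "b"])["y"].mean()
    ss_cells = sum(r * (cm - grand) ** 2 for cm in cell_means)
    ss_ab = ss_cells - ss_a - ss_b
    ss_tot = ((df["y"] - grand) ** 2).sum()
    ss_err = ss_tot - ss_cells
    df_a, df_b = A - 1, B - 1
    df_ab, df_err = df_a * df_b, n - A * B
    return {"A": (ss_a / df_a) / (ss_err / df_err),
            "B": (ss_b / df_b) / (ss_err / df_err),
            "A:B": (ss_ab / df_ab) / (ss_err / df_err)}


class TestTwoWayAnova:
    def test_constant_values(self):
        res = two_way_anova([1.0] * 8, ["a", "a", "b", "b"] * 2,
                            ["x", "y"] * 4)
        assert (res.table["F"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_degenerate_zero_variance_flags(self):
        values = [0, 0, 0, 0, 1, 1, 1, 1]
        a = ["a1"] * 4 + ["a2"] * 4
        b = ["b1", "b1", "b2", "b2"] * 2
        res = two_way_anova(values, a, b)
        assert res.degenerate
        assert res.p("A") == 0.0
        assert res.p("B") == 1.0

    def test_worked_2x3_matches_hand_sums_of_squares(self):
        values = [3, 5, 4, 6, 8, 10, 2, 2, 7, 9, 11, 15]
        a = ["a1"] * 6 + ["a2"] * 6
        b = ["b1", "b1", "b2", "b2", "b3", "b3"] * 2
        res = two_way_anova(values, a, b)
        expect = hand_anova_2x3(values, a, b)
        for term in ("A", "B", "A:B"):
            assert res.table.loc[term, "F"] == pytest.approx(expect[term], rel=1e-9)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            two_way_anova([1, 2, 3, 4], ["a"] * 4, ["x", "x", "y", "y"])

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cells"):
            two_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"],
                          ["x", "x", "x", "y"])
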