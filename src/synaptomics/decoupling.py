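"""Protein-transcript decoupling scores and coupling trajectories.

The decoupling score of a gene over a contrast is the difference of its
protein and transcript log2 fold changes (the log of the linear-scale
ratio of fold changes): positive means the protein increased more (or
decreased less) than the transcript predicts, negative the opposite.
Compartment-level coupling is tracked as per-sample Spearman correlations
between transcript RPKMs and protein intensities, compared across
compartments and ages by two-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .abundance import rpkm
from .data import COUNT_LAYERS, ExpressionMatrix


def decoupling_score(prot_log2fc, rna_log2fc):
    """score = prot_log2fc - rna_log2fc (scalars or aligned arrays).

    Sign semantics: positive when the protein increases more (or is
    reduced less) than expected from transcript regulation; negative when
    it increases less (or decreases more).
    """
    p = np.asarray(prot_log2fc, dtype=float)
    r = np.asarray(rna_log2fc, dtype=float)
    if np.any(np.isnan(p)) or np.any(np.isnan(r)):
        raise ValueError("fold changes must not be NaN")
    out = p - r
    return out.item() if out.ndim == 0 else out


def decoupling_table(rna: pd.DataFrame, prot: pd.DataFrame,
                     contrast: str = "") -> pd.DataFrame:
    """Join transcript and protein differential tables and score decoupling."""
    shared = rna.index.intersection(prot.index)
    out = pd.DataFrame({
        "rna_log2fc": rna.loc[shared, "log2fc"],
        "prot_log2fc": prot.loc[shared, "log2fc"],
    }, index=shared)
    out["decoupling"] = decoupling_score(out["prot_log2fc"].to_numpy(),
                                         out["rna_log2fc"].to_numpy())
    out.attrs["contrast"] = contrast
    out.index.name = "gene_id"
    return out


def per_gene_age_correlation(matrix: ExpressionMatrix,
                             value_kind: str | None = None) -> pd.Series:
    """Spearman rho of each gene's per-sample values against numeric age.

    ``value_kind`` is ``rpkm`` (count layers) or ``intensity`` (protein);
    inferred from the layer when omitted. Rank-based, so invariant to the
    monotone encoding of age. Genes constant across samples get NaN (with
    one summary warning).
    """
    if value_kind is None:
        value_kind = "rpkm" if matrix.layer in COUNT_LAYERS else "intensity"
    if value_kind not in ("rpkm", "intensity"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    ages = matrix.meta["age_numeric"].to_numpy(dtype=float)
    n_distinct = len(np.unique(ages))
    if n_distinct < 2:
        raise ValueError("need at least 2 distinct ages")
    if n_distinct < 3:
        warnings.warn("fewer than 3 distinct age groups; trend estimates are crude")
    if matrix.n_samples < 6:
        warnings.warn("fewer than 6 samples per gene; age correlations are noisy")
    values = rpkm(matrix) if value_kind == "rpkm" else matrix.values

    vr = values.rank(axis=1).to_numpy(dtype=float)
    ar = stats.rankdata(ages)
    vr_c = vr - vr.mean(axis=1, keepdims=True)
    ar_c = ar - ar.mean()
    denom = np.sqrt((vr_c ** 2).sum(axis=1) * (ar_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (vr_c @ ar_c) / denom
    rho[denom == 0] = np.nan
    n_bad = int(np.isnan(rho).sum())
    if n_bad:
        warnings.warn(f"{n_bad} constant gene(s): age correlation undefined")
    return pd.Series(rho, index=values.index, name="rho")


def rna_protein_coupling(rna: ExpressionMatrix, prot: ExpressionMatrix,
                         all_pairs: bool = False) -> pd.DataFrame:
    """Per-sample Spearman correlation between transcript RPKM and protein
    intensity over the shared gene set.

    By default replicate k of the RNA layer is paired with replicate k of
    the protein layer within each (compartment, age group); with
    ``all_pairs`` every RNA replicate is paired with every protein
    replicate of the same cell. Returns one row per pair with columns
    compartment, age_group, replicate (rna replicate), rho, n.
    """
    shared = rna.genes.intersection(prot.genes)
    if len(shared) == 0:
        raise ValueError("no shared genes between layers")
    rna_vals = rpkm(rna).loc[shared]
    prot_vals = prot.values.loc[shared]
    rows = []
    cells = rna.meta.groupby(["compartment", "age_group"], observed=True).groups
    for (comp, age), rna_ids in cells.items():
        prot_meta = prot.meta[(prot.meta["compartment"] == comp)
                              & (prot.meta["age_group"] == age)]
        for rna_id in rna_ids:
            rep = rna.meta.loc[rna_id, "replicate"]
            if all_pairs:
                partners = prot_meta.index.tolist()
            else:
                partners = prot_meta.index[prot_meta["replicate"] == rep].tolist()
            for prot_id in partners:
                rho, _ = stats.spearmanr(rna_vals[rna_id], prot_vals[prot_id])
                rows.append({"compartment": comp, "age_group": age,
                             "replicate": rep, "rho": float(rho), "n": len(shared)})
    return pd.DataFrame(rows)


@dataclass
class AnovaResults:
    table: pd.DataFrame  # index: term; columns F, p
    degenerate: bool = False

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def summary(self) -> str:
        lines = ["Two-way ANOVA" + (" (degenerate variance)" if self.degenerate else "")]
        for term, row in self.table.iterrows():
            lines.append(f"  {term}: F = {row['F']:.4g}, p = {row['p']:.4g}")
        return "\n".join(lines)


def two_way_anova(values, factor_a, factor_b) -> AnovaResults:
    """Fixed-effects two-way ANOVA with interaction on a (near-)balanced
    design. Returns F and p per term (A, B, A:B).

    With zero residual variance the design is degenerate: terms with
    non-zero sums of squares are reported with F = inf, p = 0 and the
    ``degenerate`` flag is set.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "A": list(factor_a), "B": list(factor_b)})
    if df["A"].nunique() < 2 or df["B"].nunique() < 2:
        raise ValueError("each factor needs at least 2 levels")
    cells = df.groupby(["A", "B"], observed=True).size()
    if len(cells) < df["A"].nunique() * df["B"].nunique():
        raise ValueError("empty factor cells: the balanced contract is violated")
    if df["value"].nunique() == 1:
        table = pd.DataFrame({"F": [0.0] * 3, "p": [1.0] * 3},
                             index=["A", "B", "A:B"])
        return AnovaResults(table)
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = sm.stats.anova_lm(model, typ=2)
    resid_ms = aov.loc["Residual", "sum_sq"] / max(aov.loc["Residual", "df"], 1)
    terms = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    rows = {}
    degenerate = resid_ms <= 1e-12
    for src, name in terms.items():
        ss = aov.loc[src, "sum_sq"]
        if degenerate:
            if ss > 1e-12:
                rows[name] = {"F": np.inf, "p": 0.0}
            else:
                rows[name] = {"F": 0.0, "p": 1.0}
        else:
            rows[name] = {"F": float(aov.loc[src, "F"]), "p": float(aov.loc[src, "PR(>F)"])}
    return AnovaResults(pd.DataFrame(rows).T[["F", "p"]], degenerate)


def coupling_anova(series: pd.DataFrame) -> AnovaResults:
    """Two-way ANOVA of per-sample coupling rho over compartment x age."""
    return two_way_anova(series["rho"], series["compartment"], series["age_group"])
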