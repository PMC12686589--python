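"""Statsmodels-style facade running the full soma/synapse integration.

`SynapticAgingAnalysis` is built from the six study matrices
({rna, ribo, protein} x {TH, SYN}); `fit()` runs the standard pipeline -
adult compartment-enrichment quadrant map, translational efficiency,
development/aging compartment-coupling correlations, per-contrast
decoupling scores, and the per-sample RNA-protein coupling ANOVA - and
returns a `SynapticAgingResults` carrying every stage's table plus a
text `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import DifferentialExpression, DifferentialResults
from .data import ExpressionMatrix
from .decoupling import (AnovaResults, coupling_anova, decoupling_table,
                         rna_protein_coupling)
from .integration import IntegrationResults, OmicsIntegration, coupling_correlation
from .translation import TEResult, delta_log2_te, translational_efficiency

#: (label, (age_A, age_B)) for the two age contrasts of the design.
AGE_CONTRASTS = {"development": ("3w", "5m"), "aging": ("5m", "18m")}


def compartment_coupling(layer_matrix: ExpressionMatrix, contrast=("3w", "5m"),
                         alpha: float = 0.05, select_on: str = "p"):
    """Spearman correlation of TH vs SYN log2 fold changes for one age
    contrast, over genes significantly regulated in either compartment.

    ``select_on`` chooses the per-layer significance column for the gene
    selection: the nominal ``p`` (default; the light-weight Welch stage has
    little adjusted-p power at small replicate numbers) or the
    BH-adjusted ``padj`` for deeper designs.

    Returns (rho, p, n_genes, per-compartment tables).
    """
    if select_on not in ("p", "padj"):
        raise ValueError(f"select_on must be 'p' or 'padj', got {select_on!r}")
    age_a, age_b = contrast
    tables = {}
    for comp in ("TH", "SYN"):
        tables[comp] = DifferentialExpression(
            layer_matrix,
            group_a={"compartment": comp, "age_group": age_a},
            group_b={"compartment": comp, "age_group": age_b},
            name=f"{comp} {age_b} vs {age_a}").fit().table
    shared = tables["TH"].index.intersection(tables["SYN"].index)
    sig = shared[(tables["TH"].loc[shared, select_on] < alpha)
                 | (tables["SYN"].loc[shared, select_on] < alpha)]
    if len(sig) < 3:
        raise ValueError(f"only {len(sig)} significant genes for contrast {contrast}")
    rho, p = coupling_correlation(tables["TH"].loc[sig, "log2fc"].to_numpy(),
                                  tables["SYN"].loc[sig, "log2fc"].to_numpy())
    return rho, p, len(sig), tables


@dataclass
class SynapticAgingResults:
    """All stage outputs of one full pipeline run."""

    integration_adult: IntegrationResults
    te_adult: TEResult
    delta_te_syn_aging: pd.Series
    coupling: pd.DataFrame  # layer x contrast: rho, p, n
    decoupling: dict  # (compartment, contrast label) -> decoupling table
    coupling_series: pd.DataFrame | None
    coupling_anova: AnovaResults | None
    differentials: dict = field(default_factory=dict)
    alpha: float = 0.05

    def summary(self) -> str:
        parts = [self.integration_adult.summary(), "", self.te_adult.summary(), ""]
        parts.append("Compartment coupling (Spearman rho of TH vs SYN log2FC, "
                     "genes significant in either compartment):")
        for _, row in self.coupling.iterrows():
            parts.append(f"  {row['layer']:8s} {row['contrast']:12s} "
                         f"rho = {row['rho']:+.3f} (p = {row['p']:.3g}, n = {row['n']})")
        parts.append("")
        for (comp, label), tab in self.decoupling.items():
            parts.append(f"Decoupling {comp} {label}: median score "
                         f"{tab['decoupling'].median():+.3f} over {len(tab)} genes")
        if self.coupling_anova is not None:
            parts += ["", self.coupling_anova.summary()]
        return "\n".join(parts)


class SynapticAgingAnalysis:
    """Model object for the full soma/synapse multi-omics integration.

    Parameters
    ----------
    matrices : mapping (layer, compartment) -> ExpressionMatrix
        The six study matrices. A `SimulatedStudy` can be passed directly.
    alpha : float
        BH significance threshold used for gene selection throughout.
    adult_age : str
        Age group of the compartment-enrichment map (default ``5m``).
    """

    def __init__(self, matrices, alpha: float = 0.05, adult_age: str = "5m"):
        matrices = getattr(matrices, "matrices", matrices)
        self.matrices = dict(matrices)
        self.alpha = alpha
        self.adult_age = adult_age

    def _layer(self, layer: str) -> ExpressionMatrix:
        return self.matrices[(layer, "TH")].concat(self.matrices[(layer, "SYN")])

    def fit(self, coupling_layers=("rna", "ribo", "protein")) -> SynapticAgingResults:
        alpha = self.alpha
        differentials = {}

        # adult SYN-vs-TH quadrant map (rna x protein)
        syn_vs_th = {}
        for layer in ("rna", "protein"):
            res = DifferentialExpression(
                self._layer(layer),
                group_a={"compartment": "TH", "age_group": self.adult_age},
                group_b={"compartment": "SYN", "age_group": self.adult_age},
                name=f"SYN vs TH ({self.adult_age})").fit()
            syn_vs_th[layer] = res
            differentials[(layer, f"SYNvsTH_{self.adult_age}")] = res
        integration = OmicsIntegration(syn_vs_th["rna"], syn_vs_th["protein"],
                                       contrast=f"SYN vs TH ({self.adult_age})",
                                       alpha=alpha).fit()

        # translational efficiency (cross-compartment, adult) and its aging change in SYN
        te_adult = translational_efficiency(self.matrices[("ribo", "SYN")],
                                            self.matrices[("ribo", "TH")],
                                            mode="cross_compartment",
                                            age_group=self.adult_age)
        te_syn = {age: translational_efficiency(self.matrices[("ribo", "SYN")],
                                                self.matrices[("rna", "SYN")],
                                                mode="within_compartment",
                                                age_group=age)
                  for age in ("5m", "18m")}
        delta_te = delta_log2_te(te_syn["18m"], te_syn["5m"])

        # compartment-coupling correlations per layer and age contrast
        rows = []
        for layer in coupling_layers:
            mat = self._layer(layer)
            for label, contrast in AGE_CONTRASTS.items():
                rho, p, n, tabs = compartment_coupling(mat, contrast, alpha)
                rows.append({"layer": layer, "contrast": label,
                             "rho": rho, "p": p, "n": n})
                for comp, tab in tabs.items():
                    differentials[(layer, f"{comp}_{contrast[1]}vs{contrast[0]}")] = \
                        DifferentialResults(tab, layer, f"{comp} {contrast[1]} vs {contrast[0]}")
        coupling = pd.DataFrame(rows)

        # per-gene decoupling scores per compartment and contrast
        decoupling = {}
        for comp in ("TH", "SYN"):
            for label, (age_a, age_b) in AGE_CONTRASTS.items():
                key_r = ("rna", f"{comp}_{age_b}vs{age_a}")
                if key_r not in differentials:
                    tab_r = DifferentialExpression(
                        self._layer("rna"),
                        group_a={"compartment": comp, "age_group": age_a},
                        group_b={"compartment": comp, "age_group": age_b}).fit().table
                else:
                    tab_r = differentials[key_r].table
                key_p = ("protein", f"{comp}_{age_b}vs{age_a}")
                if key_p not in differentials:
                    tab_p = DifferentialExpression(
                        self._layer("protein"),
                        group_a={"compartment": comp, "age_group": age_a},
                        group_b={"compartment": comp, "age_group": age_b}).fit().table
                else:
                    tab_p = differentials[key_p].table
                decoupling[(comp, label)] = decoupling_table(
                    tab_r, tab_p, contrast=f"{comp} {age_b} vs {age_a}")

        # per-sample RNA-protein coupling and its two-way ANOVA
        series = rna_protein_coupling(self._layer("rna"), self._layer("protein"))
        anova = coupling_anova(series)

        return SynapticAgingResults(
            integration_adult=integration,
            te_adult=te_adult,
            delta_te_syn_aging=delta_te,
            coupling=coupling,
            decoupling=decoupling,
            coupling_series=series,
            coupling_anova=anova,
            differentials=differentials,
            alpha=alpha,
        )
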