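"""Translational efficiency from ribosome-associated RNA and
distribution comparisons between gene classes.

TE is the ratio of ribosome-associated transcript abundance (sucrose-
cushion layer, SC) to a reference abundance, both as replicate-mean RPKM:
across compartments (SC_SYN / SC_TH) or within one compartment against the
total-RNA input (SC / input). Distributions of (log2) TE between gene
classes are compared with rank tests and visualized by Gaussian kernel
density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import rpkm
from .data import ExpressionMatrix

MODES = ("cross_compartment", "within_compartment")


@dataclass
class TEResult:
    """Per-gene translational efficiency for one numerator/denominator pair."""

    table: pd.DataFrame  # index gene_id, column 'te'
    numerator: str
    denominator: str
    age_group: str | None
    n_dropped: int  # genes removed because the denominator mean RPKM was 0

    @property
    def te(self) -> pd.Series:
        return self.table["te"]

    def log2(self) -> pd.Series:
        """log2 TE; genes with zero numerator map to -inf."""
        with np.errstate(divide="ignore"):
            return np.log2(self.table["te"]).rename("log2_te")

    def summary(self) -> str:
        return (f"Translational efficiency {self.numerator} / {self.denominator}"
                f" (age {self.age_group}): {len(self.table)} genes, "
                f"median TE {self.te.median():.3f}, {self.n_dropped} dropped "
                f"(zero denominator)")


def translational_efficiency(sc: ExpressionMatrix, reference: ExpressionMatrix,
                             mode: str = "cross_compartment",
                             age_group: str | None = "5m",
                             per_replicate: bool = False) -> TEResult:
    """TE_g = mean RPKM over numerator replicates / mean over denominator.

    ``cross_compartment``: numerator is the SYN ribosome-associated layer,
    denominator the TH ribosome-associated layer. ``within_compartment``:
    numerator is the ribosome-associated layer, denominator the total-RNA
    input of the same compartment. Samples are restricted to ``age_group``
    (None = all ages pooled). Genes whose denominator mean is 0 are dropped
    and counted in ``n_dropped``. With ``per_replicate=True`` the table
    additionally carries one TE column per replicate pair (for uncertainty
    estimation).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    for m, role in ((sc, "numerator"), (reference, "denominator")):
        if m.layer == "protein":
            raise ValueError(f"TE {role} must be a transcript layer, got 'protein'")
    if mode == "cross_compartment":
        if sc.layer != "ribo" or reference.layer != "ribo":
            raise ValueError("cross_compartment TE requires ribo layers on both sides")
    else:
        if sc.layer != "ribo" or reference.layer != "rna":
            raise ValueError("within_compartment TE requires ribo numerator and rna input")

    def mean_rpkm(mat):
        sub = mat.select(age_group=age_group) if age_group is not None else mat
        if sub.n_samples == 0:
            raise ValueError(f"no samples at age group {age_group!r}")
        return rpkm(sub), sub

    num_rpkm, num_sub = mean_rpkm(sc)
    den_rpkm, den_sub = mean_rpkm(reference)
    shared = num_rpkm.index.intersection(den_rpkm.index)
    num = num_rpkm.loc[shared].mean(axis=1)
    den = den_rpkm.loc[shared].mean(axis=1)
    keep = den > 0
    table = pd.DataFrame({"te": num[keep] / den[keep]})
    table.index.name = "gene_id"
    if per_replicate:
        reps = sorted(set(num_sub.meta["replicate"]) & set(den_sub.meta["replicate"]))
        for r in reps:
            ncol = num_rpkm.loc[shared, num_sub.sample_ids(replicate=r)].mean(axis=1)
            dcol = den_rpkm.loc[shared, den_sub.sample_ids(replicate=r)].mean(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                table[f"te_rep{r}"] = (ncol[keep] / dcol[keep]).replace(
                    [np.inf, -np.inf], np.nan)
    if mode == "cross_compartment":
        numerator, denominator = "SC_SYN", "SC_TH"
    else:
        comp = sc.meta["compartment"].iloc[0]
        numerator, denominator = f"SC_{comp}", f"input_{comp}"
    return TEResult(table, numerator, denominator, age_group,
                    n_dropped=int((~keep).sum()))


def delta_log2_te(te_old: TEResult, te_young: TEResult) -> pd.Series:
    """Per-gene change in log2 TE between two age groups (old - young)."""
    shared = te_old.table.index.intersection(te_young.table.index)
    with np.errstate(divide="ignore"):
        delta = te_old.log2().loc[shared] - te_young.log2().loc[shared]
    return delta[np.isfinite(delta)].rename("delta_log2_te")


def compare_distributions(values_by_group: dict, test: str = "wilcoxon"):
    """Rank-based comparison of value distributions between groups.

    ``wilcoxon``: two-sided Mann-Whitney rank-sum on exactly 2 groups
    (exact enumeration when both n <= 20 and there are no ties, otherwise
    the normal approximation with tie correction). ``kruskal``:
    Kruskal-Wallis H with tie correction (chi-square approximation) on
    >= 2 groups. Returns (statistic, p).
    """
    groups = [np.asarray(v, dtype=float) for v in values_by_group.values()]
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one value")
    if test == "wilcoxon":
        if len(groups) != 2:
            raise ValueError(f"wilcoxon requires exactly 2 groups, got {len(groups)}")
        a, b = groups
        pooled = np.concatenate([a, b])
        no_ties = len(np.unique(pooled)) == len(pooled)
        if no_ties and max(len(a), len(b)) <= 20:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                                 use_continuity=False)
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal":
        if len(groups) < 2:
            raise ValueError("kruskal requires at least 2 groups")
        res = stats.kruskal(*groups)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}; use 'wilcoxon' or 'kruskal'")


def kde_density(values, log_transform: bool = False, gridsize: int = 512):
    """Gaussian kernel density with Silverman bandwidth.

    Returns (grid, heights); heights integrate to 1 over the grid
    (trapezoid) to within 1e-3. With ``log_transform`` the density is
    estimated on log2 of the values (all values must be positive).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if log_transform:
        if np.any(v <= 0):
            raise ValueError("log transform requires positive values")
        v = np.log2(v)
    if np.ptp(v) == 0:
        raise ValueError("zero variance: density undefined")
    kde = stats.gaussian_kde(v, bw_method="silverman")
    h = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(v.min() - 5 * h, v.max() + 5 * h, gridsize)
    heights = kde(grid)
    return grid, heights
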