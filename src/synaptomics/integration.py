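"""Transcript-protein integration: Fisher's method, quadrant maps,
exact contingency tests, and fold-change coupling correlations.

A gene's transcript and protein contrasts are joined into a matched table;
their adjusted p-values are combined by Fisher's method (X = -2 sum ln p_i
against chi-square with 2k df), and each gene is classified into a quadrant
by the sign pair of its (transcript, protein) log2 fold changes: Q1 (+,+),
Q2 (+,-), Q3 (-,-), Q4 (-,+), named clockwise from the upper right of the
scatter. Whether the quadrant distribution departs from independence of the
two signs is tested with Fisher's exact test on the 2x2 sign table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .abundance import bh_adjust

QUADRANTS = ("Q1", "Q2", "Q3", "Q4", "boundary")

# relative slack when comparing hypergeometric masses for the two-sided sum
_TIE_EPS = 1e-7


def fisher_combine(pvals) -> float:
    """Combine k p-values with Fisher's method.

    X = -2 * sum(ln p_i); returns the upper-tail probability of a
    chi-square variate with 2k degrees of freedom at X. For k = 1 this is
    the identity (sf_chi2_2(-2 ln p) = p).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("fisher_combine requires at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, 2 * p.size))


def _fisher_combine_rows(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Row-wise Fisher combination of two p-value vectors (k = 2), kept
    strictly positive so downstream BH adjustment stays defined."""
    x = -2.0 * (np.log(pa) + np.log(pb))
    return np.clip(stats.chi2.sf(x, 4), np.nextafter(0.0, 1.0), 1.0)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Uses the probability-mass rule: the p-value sums the hypergeometric
    probabilities of all tables with the observed margins whose probability
    does not exceed that of the observed table (with a small relative
    slack for floating-point ties), computed in log space.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("cells must be non-negative")
    if not np.allclose(t, np.round(t)):
        raise ValueError("cells must be integers")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("table total must be positive")
    r1, c1 = a + b, a + c
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = stats.hypergeom.logpmf(support, n, r1, c1)
    obs = logpmf[a - lo]
    mask = logpmf <= obs + np.log1p(_TIE_EPS)
    return float(min(1.0, np.exp(logsumexp(logpmf[mask]))))


def assign_quadrants(rna_log2fc, prot_log2fc):
    """Quadrant from the ordered (transcript, protein) sign pair.

    Q1 (+,+), Q2 (+,-), Q3 (-,-), Q4 (-,+); an exact zero on either axis is
    'boundary'. Accepts scalars or aligned arrays; NaN is an error.
    """
    r = np.asarray(rna_log2fc, dtype=float)
    p = np.asarray(prot_log2fc, dtype=float)
    if np.any(~np.isfinite(r)) or np.any(~np.isfinite(p)):
        raise ValueError("fold changes must be finite")
    out = np.full(r.shape, "boundary", dtype=object)
    out[(r > 0) & (p > 0)] = "Q1"
    out[(r > 0) & (p < 0)] = "Q2"
    out[(r < 0) & (p < 0)] = "Q3"
    out[(r < 0) & (p > 0)] = "Q4"
    if out.ndim == 0:
        return out.item()
    return out


def match_omics(rna: pd.DataFrame, prot: pd.DataFrame,
                combine_on: str = "padj") -> pd.DataFrame:
    """Inner-join transcript and protein differential tables per gene.

    Combined significance is Fisher's method over the two per-layer
    adjusted p-values (``combine_on="p"`` switches to raw p-values),
    re-adjusted by BH across the joined genes; quadrants come from the sign
    pair of the log2 fold changes.
    """
    for name, tab in (("rna", rna), ("protein", prot)):
        if tab.index.has_duplicates:
            raise ValueError(f"duplicate gene_id in {name} table")
    shared = rna.index.intersection(prot.index)
    out = pd.DataFrame(index=shared)
    out.index.name = "gene_id"
    out["rna_log2fc"] = rna.loc[shared, "log2fc"]
    out["rna_padj"] = rna.loc[shared, "padj"]
    out["prot_log2fc"] = prot.loc[shared, "log2fc"]
    out["prot_padj"] = prot.loc[shared, "padj"]
    if len(shared) == 0:
        out["combined_p"] = out["combined_padj"] = []
        out["quadrant"] = []
        return out
    pa = out[f"rna_{combine_on}"].to_numpy() if combine_on == "padj" else rna.loc[shared, "p"].to_numpy()
    pb = out[f"prot_{combine_on}"].to_numpy() if combine_on == "padj" else prot.loc[shared, "p"].to_numpy()
    out["combined_p"] = _fisher_combine_rows(pa, pb)
    out["combined_padj"] = bh_adjust(out["combined_p"].to_numpy())
    out["quadrant"] = assign_quadrants(out["rna_log2fc"].to_numpy(),
                                       out["prot_log2fc"].to_numpy())
    return out


def select_significant(matched: pd.DataFrame, alpha: float = 0.05,
                       method: str = "fisher") -> pd.DataFrame:
    """Significant genes by combined (``fisher``) or per-layer
    (``intersection``) adjusted p-values."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must lie in (0, 1]")
    if method == "fisher":
        return matched[matched["combined_padj"] < alpha]
    if method == "intersection":
        return matched[(matched["rna_padj"] < alpha) & (matched["prot_padj"] < alpha)]
    raise ValueError(f"unknown method {method!r}; use 'fisher' or 'intersection'")


def quadrant_counts(matched: pd.DataFrame) -> pd.Series:
    q = matched["quadrant"]
    return q.value_counts().reindex(QUADRANTS, fill_value=0)


def quadrant_association_test(matched: pd.DataFrame) -> float:
    """Two-sided Fisher's exact p for association of the transcript and
    protein fold-change signs (rows = transcript sign, columns = protein
    sign); boundary genes are excluded."""
    counts = quadrant_counts(matched)
    if counts[["Q1", "Q2", "Q3", "Q4"]].sum() == 0:
        raise ValueError("no off-boundary genes to test")
    table = [[counts["Q1"], counts["Q2"]],
             [counts["Q4"], counts["Q3"]]]
    return fisher_exact_2x2(table)


def coupling_correlation(fc_x, fc_y):
    """Spearman rank correlation (rho, p) between two aligned per-gene
    fold-change vectors; ties get average ranks, p from the large-sample
    approximation."""
    x = np.asarray(fc_x, dtype=float)
    y = np.asarray(fc_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("vectors must be aligned 1-D arrays")
    if x.size < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class IntegrationResults:
    """Matched transcript-protein contrast with quadrant statistics."""

    matched: pd.DataFrame
    contrast: str
    alpha: float = 0.05

    @property
    def quadrant_counts(self) -> pd.Series:
        return quadrant_counts(self.matched)

    @property
    def association_p(self) -> float:
        return quadrant_association_test(self.matched)

    @property
    def scatter_spearman(self):
        return coupling_correlation(self.matched["rna_log2fc"].to_numpy(),
                                    self.matched["prot_log2fc"].to_numpy())

    def significant(self, method: str = "fisher") -> pd.DataFrame:
        return select_significant(self.matched, self.alpha, method)

    def summary(self) -> str:
        counts = self.quadrant_counts
        rho, p = self.scatter_spearman
        lines = [
            f"Transcript-protein integration - contrast {self.contrast}",
            f"  matched genes: {len(self.matched)}",
            f"  significant (Fisher combined, alpha={self.alpha}): "
            f"{len(self.significant('fisher'))}",
            "  quadrant counts: " + ", ".join(f"{q}={counts[q]}" for q in QUADRANTS),
            f"  sign-association Fisher exact p: {self.association_p:.3g}",
            f"  scatter Spearman rho: {rho:.3f} (p={p:.3g})",
        ]
        return "\n".join(lines)


class OmicsIntegration:
    """Model object joining a transcript and a protein contrast.

    Built from two differential tables (or DifferentialResults) for the
    same contrast; ``fit()`` returns :class:`IntegrationResults` with the
    matched table, quadrant counts, sign-association test and scatter
    correlation.
    """

    def __init__(self, rna, prot, contrast: str = "", alpha: float = 0.05,
                 combine_on: str = "padj"):
        self.rna = getattr(rna, "table", rna)
        self.prot = getattr(prot, "table", prot)
        self.contrast = contrast
        self.alpha = alpha
        self.combine_on = combine_on

    def fit(self) -> IntegrationResults:
        matched = match_omics(self.rna, self.prot, self.combine_on)
        return IntegrationResults(matched, self.contrast, self.alpha)
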