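"""Normalization, RPKM, and per-layer differential statistics.

The differential stage is deliberately simple and fully documented:
median-of-ratios size factors, log2(x + pseudocount) transform, Welch
two-sample t-test, Benjamini-Hochberg adjustment. All downstream
integration consumes only (log2 fold change, adjusted p), so this stage is
a contained substitution for heavier count-model fits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import COUNT_LAYERS, ExpressionMatrix

logger = logging.getLogger(__name__)

DIFF_COLUMNS = ["base_mean", "log2fc", "stat", "p", "padj", "n_A", "n_B"]


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, scaled to geometric mean 1.

    For each sample s: factor_s = median over genes positive in *all*
    samples of count_gs / geometric-mean_g(counts). If no gene is positive
    in every sample, falls back to total-count ratios with a logged warning.
    """
    arr = matrix.values.to_numpy(dtype=float)
    all_pos = np.all(arr > 0, axis=1)
    if all_pos.any():
        loggeo = np.mean(np.log(arr[all_pos]), axis=1, keepdims=True)
        ratios = np.log(arr[all_pos]) - loggeo
        logf = np.median(ratios, axis=0)
    else:
        logger.warning("size_factors: no gene positive in all samples; "
                       "falling back to total-count ratios")
        warnings.warn("size_factors falling back to total-count ratios")
        totals = arr.sum(axis=0)
        if np.any(totals <= 0):
            raise ValueError("cannot compute size factors: a sample has zero total")
        logf = np.log(totals)
    logf = logf - logf.mean()  # geometric mean 1
    return pd.Series(np.exp(logf), index=matrix.samples, name="size_factor")


def rpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    RPKM_gs = count_gs / ((length_g / 1e3) * (total_s / 1e6)).
    """
    if matrix.gene_lengths is None:
        raise ValueError(f"RPKM requires gene lengths (layer {matrix.layer!r})")
    lengths = matrix.gene_lengths
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing gene length(s): {missing[:5]}")
    totals = matrix.values.sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"zero total count in sample(s): {bad}")
    kb = lengths.to_numpy()[:, None] / 1e3
    per_m = totals.to_numpy()[None, :] / 1e6
    return pd.DataFrame(matrix.values.to_numpy(dtype=float) / (kb * per_m),
                        index=matrix.genes, columns=matrix.samples)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _resolve_group(matrix: ExpressionMatrix, group) -> list[str]:
    if isinstance(group, dict):
        return matrix.sample_ids(**group)
    return list(group)


def _welch(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch t (rows = genes) of b vs a, with the degenerate
    conventions: zero statistic -> p = 1; zero pooled variance with unequal
    means -> p -> 0."""
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = mb - ma
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = np.ones_like(t)
    ok = se2 > 0
    p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df[ok])
    degenerate = (~ok) & (diff != 0)
    t[degenerate] = np.sign(diff[degenerate]) * np.inf
    p[degenerate] = np.nextafter(0.0, 1.0)
    t[(~ok) & (diff == 0)] = 0.0
    p = np.clip(p, np.nextafter(0.0, 1.0), 1.0)
    return t, p


def differential(matrix: ExpressionMatrix, group_a, group_b,
                 pseudocount: float | None = None) -> pd.DataFrame:
    """Two-group differential table for one layer (contrast B vs A).

    Counts are normalized by median-of-ratios size factors (protein
    intensities used as-is), transformed y = log2(x + pseudocount)
    (default pseudocount 1 for counts, 0 for intensities); log2fc is
    mean(y_B) - mean(y_A) with a Welch t-test and BH adjustment across
    tested genes. Genes with zero normalized signal in both groups are
    excluded before testing.

    ``group_a``/``group_b`` are sample-ID lists or metadata-criteria dicts,
    e.g. ``{"compartment": "SYN", "age_group": "5m"}``.
    """
    ids_a = _resolve_group(matrix, group_a)
    ids_b = _resolve_group(matrix, group_b)
    if set(ids_a) & set(ids_b):
        raise ValueError(f"groups overlap: {sorted(set(ids_a) & set(ids_b))}")
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if pseudocount is None:
        pseudocount = 1.0 if matrix.layer in COUNT_LAYERS else 0.0

    sub = matrix.select(ids_a + ids_b)
    vals = sub.values.to_numpy(dtype=float)
    if matrix.layer in COUNT_LAYERS:
        sf = size_factors(sub).to_numpy()
        vals = vals / sf[None, :]

    ia = [sub.samples.get_loc(s) for s in ids_a]
    ib = [sub.samples.get_loc(s) for s in ids_b]
    mean_a = vals[:, ia].mean(axis=1)
    mean_b = vals[:, ib].mean(axis=1)
    tested = (mean_a > 0) | (mean_b > 0)

    y = np.log2(vals[tested] + pseudocount)
    t, p = _welch(y[:, ia], y[:, ib])
    out = pd.DataFrame({
        "base_mean": vals[tested].mean(axis=1),
        "log2fc": y[:, ib].mean(axis=1) - y[:, ia].mean(axis=1),
        "stat": t,
        "p": p,
        "padj": bh_adjust(p),
        "n_A": len(ids_a),
        "n_B": len(ids_b),
    }, index=matrix.genes[tested])
    out.index.name = "gene_id"
    return out


@dataclass
class DifferentialResults:
    """Results wrapper for a two-group contrast (statsmodels-style)."""

    table: pd.DataFrame
    layer: str
    contrast: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["padj"] < alpha]

    def summary(self) -> str:
        n_sig = int((self.table["padj"] < 0.05).sum())
        lines = [
            f"Differential expression - layer {self.layer}, contrast {self.contrast}",
            f"  genes tested: {len(self.table)}",
            f"  significant at BH 5%: {n_sig}",
            f"  median |log2FC|: {self.table['log2fc'].abs().median():.3f}",
        ]
        return "\n".join(lines)


class DifferentialExpression:
    """Model object: two-group differential expression on one layer.

    Examples
    --------
    >>> model = DifferentialExpression(matrix,
    ...     group_a={"compartment": "TH", "age_group": "5m"},
    ...     group_b={"compartment": "SYN", "age_group": "5m"})
    >>> res = model.fit()
    >>> res.table.head()
    """

    def __init__(self, matrix: ExpressionMatrix, group_a, group_b,
                 pseudocount: float | None = None, name: str = "B_vs_A"):
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b
        self.pseudocount = pseudocount
        self.name = name

    def fit(self) -> DifferentialResults:
        table = differential(self.matrix, self.group_a, self.group_b,
                             self.pseudocount)
        return DifferentialResults(table, self.matrix.layer, self.name)
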