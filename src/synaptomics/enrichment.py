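"""Gene-set statistics on per-gene scores and hit lists.

Two complementary tests:

* a set-vs-background two-sample t-test on per-gene scores (fold changes,
  age-correlation rhos, decoupling scores): does the set's mean score
  differ from the rest of the universe? (the GAGE idea);
* overrepresentation (ORA): hypergeometric upper-tail probability that a
  hit list overlaps a set at least as much as observed.

Plus the unique-vs-shared list-overlap comparison between two contrasts
(Fisher's exact test on the 2x2 of unique/shared counts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .abundance import bh_adjust
from .data import GeneSetCollection
from .integration import fisher_exact_2x2


def gage_test(scores: pd.Series, gene_set, universe=None,
              background: str = "disjoint"):
    """Set-vs-background Welch t-test on per-gene scores.

    Returns (t, p, direction) with two-sided p and direction 'up'/'down'
    by the sign of mean(set) - mean(background). The background is the
    universe minus the set (``background="disjoint"``, default) or the
    whole universe (``background="universe"``). The set must retain >= 2
    members after intersection with the universe.
    """
    scores = pd.Series(scores).astype(float).dropna()
    uni = scores.index if universe is None else pd.Index(universe).intersection(scores.index)
    members = [g for g in dict.fromkeys(gene_set) if g in set(uni)]
    if len(members) < 2:
        raise ValueError(f"gene set has {len(members)} member(s) in the universe; need >= 2")
    set_scores = scores.loc[members].to_numpy()
    if background == "disjoint":
        bg_index = uni.difference(members)
    elif background == "universe":
        bg_index = uni
    else:
        raise ValueError(f"unknown background {background!r}")
    bg_scores = scores.loc[bg_index].to_numpy()
    if len(bg_scores) < 2:
        raise ValueError("background has fewer than 2 genes")
    diff = set_scores.mean() - bg_scores.mean()
    if set_scores.var(ddof=1) == 0 and bg_scores.var(ddof=1) == 0:
        if diff == 0:
            return 0.0, 1.0, "up"
        return np.sign(diff) * np.inf, np.nextafter(0.0, 1.0), "up" if diff > 0 else "down"
    t, p = stats.ttest_ind(set_scores, bg_scores, equal_var=False)
    p = min(max(float(p), np.nextafter(0.0, 1.0)), 1.0)  # guard underflow
    return float(t), p, "up" if diff >= 0 else "down"


def ora_test(hits, gene_set, universe):
    """Hypergeometric overrepresentation of a hit list in a gene set.

    Returns (overlap, fold_enrichment, p) where p is the upper-tail
    probability of drawing at least the observed overlap:
    p = P(X >= k) = 1 - CDF(k - 1). Empty hit lists return p = 1 with a
    warning (flagged convention).
    """
    uni = list(dict.fromkeys(universe))
    uniset = set(uni)
    hits_u = [g for g in dict.fromkeys(hits) if g in uniset]
    members = [g for g in dict.fromkeys(gene_set) if g in uniset]
    if len(hits_u) == 0:
        warnings.warn("empty hit list: ORA p set to 1 by convention")
        return 0, np.nan, 1.0
    k = len(set(hits_u) & set(members))
    M, K, n = len(uni), len(members), len(hits_u)
    p = float(stats.hypergeom.sf(k - 1, M, K, n))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    fold = (k / n) / (K / M) if K > 0 else np.nan
    return k, fold, p


def enrich_collection(scores_or_hits, collection: GeneSetCollection,
                      method: str = "gage", universe=None,
                      background: str = "disjoint") -> pd.DataFrame:
    """Apply a set test across a collection with BH adjustment.

    ``method="gage"`` takes a per-gene score Series (its index is the
    default universe) and reports t, two-sided p, both one-sided p-values
    and the direction; ``method="ora"`` takes a hit list (``universe``
    required) and reports overlap, fold enrichment and the hypergeometric
    p. Rows are sorted by p with ties broken by set name (deterministic).
    """
    if method not in ("gage", "ora"):
        raise ValueError(f"unknown method {method!r}")
    if method == "gage":
        scores = pd.Series(scores_or_hits).astype(float)
        uni = scores.index if universe is None else pd.Index(universe)
    else:
        if universe is None:
            raise ValueError("ORA requires an explicit universe")
        uni = pd.Index(list(dict.fromkeys(universe)))
    coll = collection.filtered(uni, collection.min_size)
    if len(coll) == 0:
        raise ValueError("no gene sets left after filtering to the universe")
    rows = []
    for name, members in coll:
        if method == "gage":
            t, p, direction = gage_test(scores, members, uni, background)
            # one-sided tails from the two-sided Welch p
            p_up = p / 2 if t >= 0 else 1 - p / 2
            rows.append({"set_name": name, "set_size": len(members), "stat": t,
                         "p": p, "p_up": p_up, "p_down": 1 - p_up,
                         "direction": direction})
        else:
            k, fold, p = ora_test(scores_or_hits, members, uni)
            rows.append({"set_name": name, "set_size": len(members),
                         "overlap": k, "fold_enrichment": fold, "stat": fold,
                         "p": p})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"].to_numpy())
    out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    return out


def overlap_comparison(unique_1: int, shared_1: int,
                       unique_2: int, shared_2: int):
    """Compare the unique fraction of two lists (e.g. genes with
    differential junctions that are not differentially expressed, in two
    age contrasts).

    Returns ((pct_unique_1, pct_unique_2), fisher_p) where percentages are
    unique / (unique + shared) * 100 and p is the two-sided Fisher's exact
    test on [[unique_1, shared_1], [unique_2, shared_2]].
    """
    cells = (unique_1, shared_1, unique_2, shared_2)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    if unique_1 + shared_1 == 0 or unique_2 + shared_2 == 0:
        raise ValueError("each pair's total must be positive")
    pct1 = 100.0 * unique_1 / (unique_1 + shared_1)
    pct2 = 100.0 * unique_2 / (unique_2 + shared_2)
    p = fisher_exact_2x2([[unique_1, shared_1], [unique_2, shared_2]])
    return (pct1, pct2), p


@dataclass
class EnrichmentResults:
    """Results of a collection-wide set test."""

    table: pd.DataFrame
    method: str

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["padj"] < alpha]

    def summary(self) -> str:
        sig = self.significant()
        lines = [f"Gene-set enrichment ({self.method}): {len(self.table)} sets tested, "
                 f"{len(sig)} significant at BH 5%"]
        for _, row in sig.head(10).iterrows():
            extra = (f"direction={row['direction']}" if self.method == "gage"
                     else f"overlap={row['overlap']}")
            lines.append(f"  {row['set_name']} (n={row['set_size']}): "
                         f"padj={row['padj']:.3g}, {extra}")
        return "\n".join(lines)


class GeneSetEnrichment:
    """Model object: per-gene scores (or a hit list) against a collection."""

    def __init__(self, scores_or_hits, collection: GeneSetCollection,
                 method: str = "gage", universe=None, background: str = "disjoint"):
        self.scores_or_hits = scores_or_hits
        self.collection = collection
        self.method = method
        self.universe = universe
        self.background = background

    def fit(self) -> EnrichmentResults:
        table = enrich_collection(self.scores_or_hits, self.collection,
                                  self.method, self.universe, self.background)
        return EnrichmentResults(table, self.method)
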