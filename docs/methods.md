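# Methods

## The analysis problem

Neurons translate many mRNAs locally at synapses, and subcellular
fractionation (synaptosome preparations, SYN) paired with total homogenate
(TH) makes the soma-vs-synapse axis measurable with bulk omics. The package
integrates three molecular layers measured in both compartments across
three ages (weaning ~3 weeks, mature adult ~5 months, old ~18 months):

* **rna** — total transcriptome counts,
* **ribo** — ribosome-associated transcriptome counts (sucrose-cushion
  pull-down, "SC" layers),
* **protein** — mass-spectrometry intensities.

The questions it answers are: which genes are enriched or depleted at the
synapse at the transcript and/or protein level (the quadrant map); which
transcripts are translationally repressed at the synapse (translational
efficiency, TE); whether protein changes track transcript changes over age
(decoupling scores, RNA–protein coupling correlations); and whether the
synaptic compartment follows the soma during development but not during
aging (compartment-coupling trajectories).

## Statistical procedures

**Differential stage.** Counts are normalized with median-of-ratios size
factors (computed over genes positive in every sample, rescaled to
geometric mean 1; total-count fallback when no such gene exists). Values
are transformed `y = log2(x + pseudocount)` (pseudocount 1 for counts, 0
for intensities, which are positive); the per-gene contrast is
`log2FC = mean(y_B) − mean(y_A)` with a Welch two-sample t-test and
Benjamini–Hochberg adjustment over tested genes (tested = normalized mean
positive in at least one group). This is a deliberately transparent
substitute for count-model fits (dispersion shrinkage, Wald tests): every
downstream stage consumes only `(log2FC, p, padj)`, so the substitution is
contained. Degenerate cases follow fixed conventions: zero statistic →
p = 1; zero variance with unequal means → p clipped to the smallest
positive float.

**Cross-omics integration.** Transcript and protein contrast tables are
inner-joined per gene. Significance is combined with Fisher's method,
`X = −2 Σ ln p_i ~ χ²(2k)`, applied to the two BH-adjusted p-values —
statistically unconventional, but it is the combination the upstream
selection uses in this pipeline; a `combine_on="p"` flag switches to raw
p-values. The combined p is re-adjusted by BH across joined genes.
Quadrants are the ordered sign pair (transcript, protein): Q1 (+,+),
Q2 (+,−), Q3 (−,−), Q4 (−,+), clockwise from the upper right of the
scatter; exact zeros are `boundary`. Departure of the quadrant
distribution from sign independence is tested with a two-sided Fisher's
exact test on the 2×2 sign table (rows = transcript sign, columns =
protein sign) — the only 2×2 reduction consistent with a four-quadrant
"uniformity" test. The two-sided exact test uses the probability-mass
rule (sum over tables with the observed margins whose hypergeometric mass
does not exceed the observed one, with 1e-7 relative slack for
floating-point ties), evaluated in log space; it is verified against
exact-integer enumeration for every table with total ≤ 40.

**Translational efficiency.** `TE_g` is the ratio of replicate-mean RPKM
(`count / (kb · million mapped reads)`) of the ribosome-associated layer
to a reference: across compartments (`SC_SYN / SC_TH`) or against the
total-RNA input within one compartment. Replicate-mean ratios (one TE per
gene) are the primary output; per-replicate ratios are available behind a
flag for uncertainty estimates. Genes with zero denominator are dropped
and counted. Distribution comparisons between gene classes use the
Mann–Whitney rank-sum (exact enumeration when both groups are ≤ 20 without
ties, otherwise the tie-corrected normal approximation without continuity
correction, so identical groups give p = 1) or Kruskal–Wallis; densities
use a Gaussian kernel with Silverman bandwidth on log2 values.

**Decoupling.** The per-gene decoupling score over a contrast is
`prot_log2FC − rna_log2FC` — the log of the linear-scale ratio of fold
changes. A literal ratio of signed log-fold-changes would violate the
intended sign semantics when both changes are negative (protein falling
faster than transcript must be negative), which the difference form
satisfies in all four sign combinations. Per-gene age trends are Spearman
correlations of per-sample values (RPKM or intensity) against numeric age;
being rank-based they are invariant to the age encoding (defaults 21, 150,
540 days). Per-sample RNA–protein coupling pairs RNA replicate k with
protein replicate k within each (compartment, age) cell (an all-pairs
variant is available); the resulting correlations are compared by a
fixed-effects two-way ANOVA (compartment × age, with interaction; type-II
sums of squares, equal to type-I under balance).

**Gene-set statistics.** The set test on per-gene scores (fold changes,
age-trend rhos, decoupling scores) is a Welch two-sample t-test of set
members against the disjoint background (universe minus set; a flag allows
the whole universe), reported two-sided with both one-sided tails and a
direction — the described behaviour of GAGE-style enrichment, not a
re-implementation of that package's internal one-on-one sample
comparisons. Overrepresentation uses the hypergeometric upper tail
`P(X ≥ k)` with fold enrichment `(k/n)/(K/M)`. Collections are filtered to
sets with ≥ 5 members in the universe; BH adjustment runs across tested
sets; output order is (p, set name) for determinism. List-overlap
comparisons (e.g. genes with differential junctions that are not
differentially expressed, in two contrasts) use the two-sided exact test
on the `[[unique1, shared1], [unique2, shared2]]` table.

## The synthetic study generator

The generator emulates the study design so every stage is testable without
the deposited data: 3 ages × 2 compartments × 3 layers × `n_reps = 4`
replicates, `n_genes = 2000`. Genes belong to functional classes
(synaptic 15%, ribosomal 5%, respiratory 5%, vesicle 5%, nuclear 10%,
background 60%) assigned deterministically by rounded counts.

* **Counts** are negative-binomial with `log2` mean
  `base + compartment effect + accumulated age effects + library offset`,
  `base ~ Normal(5, 2)`, dispersion `φ(μ) = 0.1 + 1/μ`
  (`var = μ + φμ²`), and per-sample library offsets uniform on
  ±0.25 log2 (≤ √2-fold spread, so normalization is exercised).
* **Compartment effects** (SYN vs TH, log2) encode the quadrant classes:
  synaptic (+1 rna, +1 protein), ribosomal and respiratory (+1, −1),
  vesicle (−1, +1), nuclear (−1, −1), background (0, 0).
* **Development (3w→5m)** effects ~ Normal(0, 0.5) hit 30% of genes and
  are applied to both compartments — development is soma-driven and
  coupled. **Aging (5m→18m)** effects are drawn independently per
  compartment (decoupled), except the programmed ribosomal/respiratory
  pattern: TH rna +0.5, TH protein −0.75, SYN rna −0.75, SYN protein
  +0.75 — the headline transcript-down / protein-up synaptic aging
  signature.
* **Ribosome-associated means** equal the rna means plus a TE offset:
  −1.5 log2 in SYN for ribosomal/respiratory genes at 3w and 5m,
  partially released (+0.75) at 18m. The release ties the old-SYN protein
  gain to increased ribosome association, which is what makes the
  decoupling-vs-ΔTE correlation a meaningful recovery target; without an
  age-dependent TE offset that correlation would be identically zero.
* **Protein intensities** are log-normal:
  `log2 intensity = 16 + 0.8·(base TH rna mean) + class compartment
  effect + 0.8·(development effect) + aging effect + Normal(0, 0.5)`,
  where the aging effect is the programmed class pattern where defined and
  otherwise `0.8 ×` the TH transcript aging effect (soma-driven
  synthesis). Only the top 60% of genes by mean programmed intensity are
  detected; the rest are genuinely absent from the protein matrices, not
  zero, reproducing partial proteome depth. Synaptically depleted
  proteins rank lower, so their classes are slightly under-covered — as
  in real DIA data.

`SimTruth` records every programmed class and effect, and
`truth_labels` exposes the recovery questions (programmed quadrant,
decoupled aging set, translationally repressed set). The same seed gives
bit-identical output.

**What the generator does not emulate:** peptide-level MS structure and
imputation, junction-level splicing, ortholog/ID mapping mismatches
between protein groups and transcripts, batch structure, or age-dependent
measurement noise. Passing recovery tests therefore show that the
statistics recover the programmed population structure under realistic
count/intensity noise — not that they would recover effects of this size
in data with those additional complications.

## Selection for coupling trajectories, and a known limitation

The compartment-coupling correlation (Spearman of TH vs SYN log2 fold
changes per age contrast) is computed over genes significantly regulated
in either compartment. With four replicates the Welch stage has very
little BH-adjusted power (the best attainable |z| for a 0.5-log2 effect at
this dispersion is ≈ 1.2), so the selection uses the nominal per-layer
p < α by default (`select_on="padj"` is available for deeper designs).
Even so, the development correlation is attenuated by fold-change
estimation noise: with per-compartment estimation error sd ≈ 0.45 and a
shared effect sd of 0.5, the attainable correlation among truly co-regulated
genes is ≈ Var(e)/(Var(e)+σ²) ≈ 0.6, and the realized value over the
selected set is ≈ 0.45. The qualitative contrast — development strongly
coupled, aging near zero — is robust across seeds and layers; the absolute
development value should be read with that attenuation in mind.

## Problem sizes and numerical choices

All simulations and tests run at the default study conditions
(2000 genes × 4 replicates); the permutation calibration uses 100
permutations of 40 random sets over 2000 genes, and the exact-test
enumeration sweep covers all 135,750 tables with total ≤ 40. Ties in rank
statistics use average ranks; p-values that underflow to zero are clipped
to the smallest positive float so BH stays defined; gene selection ties in
enrichment output are broken by set name for byte-identical reruns.
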