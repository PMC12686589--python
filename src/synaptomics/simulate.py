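"""Synthetic paired multi-omics study generator with ground truth.

Emulates the design of the soma/synapse aging study: three age groups
(3w, 5m, 18m), two compartments (TH total homogenate, SYN synaptosome),
three layers (rna, ribo, protein), n replicates per cell. Counts are
negative-binomial, protein intensities log-normal. Genes belong to
functional classes with programmed compartment-enrichment signs (the
quadrant structure), and age effects are constructed so that development
(3w -> 5m) is coupled between compartments while aging (5m -> 18m) is
decoupled, with ribosomal/respiratory classes carrying the headline
transcript-down / protein-up synaptic aging pattern and an age-dependent
translational-efficiency shift.

The generator's defaults define the study conditions every recovery and
calibration test runs under; `SimTruth` records the programmed class and
effect of every gene so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd

from .data import AGE_DAYS, AGE_GROUPS, COMPARTMENTS, ExpressionMatrix, GeneSetCollection

CLASSES = ("synaptic", "ribosomal", "respiratory", "vesicle", "nuclear", "background")

#: Programmed SYN-vs-TH compartment effects (log2) per class, (rna, protein).
#: The sign pairs place each class in its quadrant of the adult SYN-vs-TH map:
#: synaptic Q1 (+,+), ribosomal/respiratory Q2 (+,-), nuclear Q3 (-,-),
#: vesicle Q4 (-,+). The ribo layer follows rna plus the TE offset.
DEFAULT_COMPARTMENT_EFFECTS = {
    "synaptic": {"rna": 1.0, "protein": 1.0},
    "ribosomal": {"rna": 1.0, "protein": -1.0},
    "respiratory": {"rna": 1.0, "protein": -1.0},
    "vesicle": {"rna": -1.0, "protein": 1.0},
    "nuclear": {"rna": -1.0, "protein": -1.0},
    "background": {"rna": 0.0, "protein": 0.0},
}

#: Programmed 5m -> 18m aging effects (log2) for the decoupled classes,
#: keyed (class, compartment, layer): TH transcripts up / proteins down,
#: SYN transcripts down / proteins up.
DEFAULT_AGING_EFFECTS = {
    ("ribosomal", "TH", "rna"): 0.5,
    ("ribosomal", "TH", "protein"): -0.75,
    ("ribosomal", "SYN", "rna"): -0.75,
    ("ribosomal", "SYN", "protein"): 0.75,
    ("respiratory", "TH", "rna"): 0.5,
    ("respiratory", "TH", "protein"): -0.75,
    ("respiratory", "SYN", "rna"): -0.75,
    ("respiratory", "SYN", "protein"): 0.75,
}


def default_dispersion(mu: np.ndarray) -> np.ndarray:
    """Negative-binomial dispersion phi as a function of the mean:
    var = mu + phi(mu) * mu^2, with phi(mu) = 0.1 + 1/mu."""
    return 0.1 + 1.0 / np.maximum(mu, 1e-8)


@dataclass
class SimParams:
    """Parameters of the synthetic study.

    Defaults are the study conditions used throughout the test suite; see
    the methods note for the rationale behind each value.
    """

    n_genes: int = 2000
    n_reps: int = 4
    class_fractions: dict = field(default_factory=lambda: {
        "synaptic": 0.15, "ribosomal": 0.05, "respiratory": 0.05,
        "vesicle": 0.05, "nuclear": 0.10, "background": 0.60,
    })
    base_log2_mean_loc: float = 5.0
    base_log2_mean_scale: float = 2.0
    nb_dispersion: Callable[[np.ndarray], np.ndarray] = default_dispersion
    protein_coupling_slope: float = 0.8
    protein_noise_sd_log2: float = 0.5
    protein_intercept_log2: float = 16.0
    compartment_effects_log2: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMPARTMENT_EFFECTS.items()})
    dev_effect_sd_log2: float = 0.5
    dev_effect_fraction: float = 0.30
    aging_effect_sd_log2: float = 0.5
    aging_effect_fraction: float = 0.30
    aging_effects_log2: dict = field(default_factory=lambda: dict(DEFAULT_AGING_EFFECTS))
    #: log2 TE offset of ribosome-associated vs total RNA in SYN for the
    #: translationally repressed classes (applied at 3w and 5m).
    te_repression_log2: float = -1.5
    #: log2 release of that repression at 18m (drives the old-SYN protein
    #: gain through increased ribosome association).
    te_release_log2: float = 0.75
    te_repressed_classes: tuple = ("ribosomal", "respiratory")
    proteome_depth_fraction: float = 0.6
    library_size_log2_spread: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if any(not (0.0 <= f <= 1.0) for f in self.class_fractions.values()):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2")
        if np.any(self.nb_dispersion(np.array([1.0, 100.0])) <= 0):
            raise ValueError("dispersion must be positive")

    def null(self) -> "SimParams":
        """A copy with every programmed effect zeroed (global null)."""
        zero_comp = {k: {"rna": 0.0, "protein": 0.0} for k in self.class_fractions}
        return replace(
            self,
            compartment_effects_log2=zero_comp,
            dev_effect_fraction=0.0,
            aging_effect_fraction=0.0,
            aging_effects_log2={},
            te_repression_log2=0.0,
            te_release_log2=0.0,
        )


@dataclass
class SimulatedStudy:
    """Six expression matrices ({rna, ribo, protein} x {TH, SYN}) + truth."""

    matrices: dict
    truth: pd.DataFrame
    params: SimParams

    def matrix(self, layer: str, compartment: str) -> ExpressionMatrix:
        return self.matrices[(layer, compartment)]

    def layer(self, layer: str) -> ExpressionMatrix:
        """TH and SYN matrices of one layer concatenated."""
        return self.matrix(layer, "TH").concat(self.matrix(layer, "SYN"))


def _class_labels(params: SimParams) -> np.ndarray:
    """Deterministic class assignment by counts (rounded fractions, remainder
    to background), in CLASSES order along the gene index."""
    n = params.n_genes
    counts = {}
    for cls in CLASSES:
        if cls == "background":
            continue
        counts[cls] = int(round(params.class_fractions.get(cls, 0.0) * n))
    counts["background"] = n - sum(counts.values())
    if counts["background"] < 0:
        raise ValueError("class fractions round to more genes than n_genes")
    labels = np.empty(n, dtype=object)
    i = 0
    for cls in CLASSES:
        c = counts.get(cls, 0)
        labels[i:i + c] = cls
        i += c
    return labels


def _nb_counts(rng: np.random.Generator, mu: np.ndarray,
               dispersion: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    phi = dispersion(mu)
    shape = 1.0 / phi
    lam = rng.gamma(shape=shape, scale=mu / shape)
    return rng.poisson(lam).astype(float)


def simulate_study(params: SimParams | None = None) -> SimulatedStudy:
    """Generate the six matrices and the ground-truth table.

    Construction (all effects in log2 units):

    * per-gene base log2 mean ~ Normal(5, 2); transcript means add the
      class compartment effect in SYN;
    * development (3w -> 5m) effects are drawn once per affected gene and
      applied to BOTH compartments (coupled); aging (5m -> 18m) effects are
      drawn independently per compartment (decoupled), except the
      programmed ribosomal/respiratory patterns;
    * ribo-layer means equal rna-layer means shifted by the TE offsets
      (repression in SYN for the repressed classes, partially released at
      18m);
    * protein log2 intensity = intercept + slope * (base TH rna log2 mean)
      + class protein compartment effect + slope-propagated development
      effect + aging effect (programmed pattern where defined, otherwise
      slope * TH transcript aging effect) + Normal(0, sd) noise; only the
      top ``proteome_depth_fraction`` of genes by mean intensity are
      detected (others are absent from the protein matrices);
    * counts ~ NB(mean, phi(mean)) after a per-sample library-size offset.

    The same seed yields bit-identical output.
    """
    if params is None:
        params = SimParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_genes
    genes = pd.Index([f"G{i:05d}" for i in range(n)], name="gene_id")
    classes = _class_labels(params)

    base = rng.normal(params.base_log2_mean_loc, params.base_log2_mean_scale, size=n)
    lengths = pd.Series(
        np.clip(np.round(2 ** rng.normal(11.0, 0.8, size=n)), 200, 100000),
        index=genes, name="length")

    comp_rna = np.array([params.compartment_effects_log2[c]["rna"] for c in classes])
    comp_prot = np.array([params.compartment_effects_log2[c]["protein"] for c in classes])

    # development: coupled between compartments, one draw per affected gene
    dev_mask = rng.random(n) < params.dev_effect_fraction
    dev = np.where(dev_mask, rng.normal(0.0, params.dev_effect_sd_log2, size=n), 0.0)

    # aging: independent draws per compartment; programmed classes override
    aging = {}
    for comp in COMPARTMENTS:
        mask = rng.random(n) < params.aging_effect_fraction
        eff = np.where(mask, rng.normal(0.0, params.aging_effect_sd_log2, size=n), 0.0)
        prog = np.array([params.aging_effects_log2.get((c, comp, "rna"), np.nan)
                         for c in classes])
        aging[comp] = np.where(np.isnan(prog), eff, prog)

    # TE offsets (ribo vs rna in SYN), by age
    repressed = np.isin(classes, params.te_repressed_classes)
    te_offset = {
        "3w": np.where(repressed, params.te_repression_log2, 0.0),
        "5m": np.where(repressed, params.te_repression_log2, 0.0),
        "18m": np.where(repressed, params.te_repression_log2 + params.te_release_log2, 0.0),
    }

    # protein aging effects: programmed pattern where defined, otherwise the
    # slope-propagated TH transcript aging effect (soma-driven synthesis)
    prot_aging = {}
    for comp in COMPARTMENTS:
        prog = np.array([params.aging_effects_log2.get((c, comp, "protein"), np.nan)
                         for c in classes])
        prot_aging[comp] = np.where(np.isnan(prog),
                                    params.protein_coupling_slope * aging["TH"], prog)

    def age_cum(per_age_dev, per_age_aging, age):
        if age == "3w":
            return 0.0
        if age == "5m":
            return per_age_dev
        return per_age_dev + per_age_aging

    # log2 mean tables per (layer, compartment, age)
    rna_mean = {}
    for comp in COMPARTMENTS:
        comp_eff = comp_rna if comp == "SYN" else 0.0
        for age in AGE_GROUPS:
            rna_mean[(comp, age)] = base + comp_eff + age_cum(dev, aging[comp], age)

    ribo_mean = {}
    for comp in COMPARTMENTS:
        for age in AGE_GROUPS:
            off = te_offset[age] if comp == "SYN" else 0.0
            ribo_mean[(comp, age)] = rna_mean[(comp, age)] + off

    slope = params.protein_coupling_slope
    prot_mean = {}
    for comp in COMPARTMENTS:
        comp_eff = comp_prot if comp == "SYN" else 0.0
        for age in AGE_GROUPS:
            prot_mean[(comp, age)] = (
                params.protein_intercept_log2 + slope * base + comp_eff
                + age_cum(slope * dev, prot_aging[comp], age))

    # proteome depth: top fraction of genes by mean programmed intensity
    mean_int = np.mean([prot_mean[k] for k in prot_mean], axis=0)
    n_det = int(round(params.proteome_depth_fraction * n))
    order = np.argsort(-mean_int, kind="stable")
    detected = np.zeros(n, dtype=bool)
    detected[order[:n_det]] = True

    matrices = {}
    for layer, means in (("rna", rna_mean), ("ribo", ribo_mean)):
        for comp in COMPARTMENTS:
            cols, metas = [], []
            for age in AGE_GROUPS:
                for rep in range(1, params.n_reps + 1):
                    lib = rng.uniform(-params.library_size_log2_spread / 2,
                                      params.library_size_log2_spread / 2)
                    mu = 2.0 ** (means[(comp, age)] + lib)
                    cols.append(_nb_counts(rng, mu, params.nb_dispersion))
                    metas.append({"sample_id": f"{layer}_{comp}_{age}_r{rep}",
                                  "compartment": comp, "age_group": age,
                                  "age_numeric": AGE_DAYS[age], "layer": layer,
                                  "replicate": rep})
            values = pd.DataFrame(np.column_stack(cols), index=genes,
                                  columns=[m["sample_id"] for m in metas])
            meta = pd.DataFrame(metas).set_index("sample_id")
            matrices[(layer, comp)] = ExpressionMatrix(values, meta, layer, lengths)

    det_genes = genes[detected]
    for comp in COMPARTMENTS:
        cols, metas = [], []
        for age in AGE_GROUPS:
            for rep in range(1, params.n_reps + 1):
                noise = rng.normal(0.0, params.protein_noise_sd_log2, size=n)
                cols.append(2.0 ** (prot_mean[(comp, age)] + noise))
                metas.append({"sample_id": f"protein_{comp}_{age}_r{rep}",
                              "compartment": comp, "age_group": age,
                              "age_numeric": AGE_DAYS[age], "layer": "protein",
                              "replicate": rep})
        values = pd.DataFrame(np.column_stack(cols), index=genes,
                              columns=[m["sample_id"] for m in metas]).loc[det_genes]
        meta = pd.DataFrame(metas).set_index("sample_id")
        matrices[("protein", comp)] = ExpressionMatrix(values, meta, "protein")

    truth = pd.DataFrame({
        "class": classes,
        "base_log2_mean": base,
        "comp_effect_rna": comp_rna,
        "comp_effect_protein": comp_prot,
        "dev_effect": dev,
        "aging_effect_rna_TH": aging["TH"],
        "aging_effect_rna_SYN": aging["SYN"],
        "aging_effect_protein_TH": prot_aging["TH"],
        "aging_effect_protein_SYN": prot_aging["SYN"],
        "te_offset_young": te_offset["3w"],
        "te_offset_old": te_offset["18m"],
        "protein_detected": detected,
    }, index=genes)
    return SimulatedStudy(matrices, truth, params)


TRUTH_QUESTIONS = ("quadrant_adult_SYNvsTH", "decoupled_aging_SYN", "te_repressed_young")


def truth_labels(truth: pd.DataFrame, question: str) -> pd.Series:
    """Ground-truth label per gene for a recovery question.

    * ``quadrant_adult_SYNvsTH``: programmed quadrant of the adult SYN-vs-TH
      map from the compartment-effect sign pair ('none' for background);
    * ``decoupled_aging_SYN``: True for the programmed decoupled classes
      (ribosomal + respiratory);
    * ``te_repressed_young``: True for the translationally repressed classes.
    """
    if question not in TRUTH_QUESTIONS:
        raise ValueError(f"unknown question {question!r}; supported: {TRUTH_QUESTIONS}")
    if question == "quadrant_adult_SYNvsTH":
        def quad(row):
            r, p = row["comp_effect_rna"], row["comp_effect_protein"]
            if r > 0 and p > 0:
                return "Q1"
            if r > 0 and p < 0:
                return "Q2"
            if r < 0 and p < 0:
                return "Q3"
            if r < 0 and p > 0:
                return "Q4"
            return "none"
        return truth.apply(quad, axis=1).rename("quadrant")
    decoupled = truth["class"].isin(["ribosomal", "respiratory"])
    if question == "decoupled_aging_SYN":
        return decoupled.rename("decoupled")
    return decoupled.rename("te_repressed")


def truth_gene_sets(truth: pd.DataFrame, min_size: int = 5) -> GeneSetCollection:
    """Gene sets of the programmed classes (for enrichment recovery tests)."""
    sets = {cls: truth.index[truth["class"] == cls].tolist()
            for cls in CLASSES if cls != "background"}
    return GeneSetCollection({k: v for k, v in sets.items() if len(v) >= min_size},
                             min_size)
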