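"""Core data model and I/O for compartment multi-omics studies.

The study design is gene x sample matrices for three molecular layers
(``rna``: total transcriptome counts, ``ribo``: ribosome-associated
transcriptome counts, ``protein``: mass-spec intensities), measured in two
subcellular compartments (``TH`` total homogenate, ``SYN`` synaptosome)
across three age groups (``3w``, ``5m``, ``18m``) with replicate animals.

Matrices travel as tab-separated tables (genes in the first column, sample
IDs in the header) accompanied by a sample-metadata table; gene sets travel
in GMT format.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

COMPARTMENTS = ("TH", "SYN")
AGE_GROUPS = ("3w", "5m", "18m")
LAYERS = ("rna", "ribo", "protein")
COUNT_LAYERS = ("rna", "ribo")

#: Default numeric ages in days. All rank-based statistics are invariant to
#: this choice; it only matters for plotting and bookkeeping.
AGE_DAYS = {"3w": 21.0, "5m": 150.0, "18m": 540.0}

META_COLUMNS = ["compartment", "age_group", "age_numeric", "layer", "replicate"]


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sample (one animal x compartment x layer)."""

    sample_id: str
    compartment: str
    age_group: str
    layer: str
    replicate: int
    age_numeric: float = 0.0

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}; expected one of {COMPARTMENTS}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age_group {self.age_group!r}; expected one of {AGE_GROUPS}")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")
        if self.age_numeric == 0.0:
            object.__setattr__(self, "age_numeric", AGE_DAYS[self.age_group])


def _meta_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": s.sample_id,
            "compartment": s.compartment,
            "age_group": s.age_group,
            "age_numeric": s.age_numeric,
            "layer": s.layer,
            "replicate": s.replicate,
        }
        for s in samples
    ]
    return pd.DataFrame(rows).set_index("sample_id")


class ExpressionMatrix:
    """Gene x sample values for a single molecular layer.

    Parameters
    ----------
    values : pandas.DataFrame
        Non-negative values, genes on the index, sample IDs on the columns.
        Counts for the ``rna``/``ribo`` layers, intensities for ``protein``.
    meta : pandas.DataFrame or sequence of SampleMeta
        One row per sample (indexed by sample ID) with columns
        ``compartment``, ``age_group``, ``age_numeric``, ``layer``,
        ``replicate``. Column order of ``values`` is aligned to ``meta``.
    layer : str
        One of ``rna``, ``ribo``, ``protein``; all samples must share it.
    gene_lengths : pandas.Series, optional
        Transcript length in base pairs per gene; required for RPKM on the
        count layers, absent for protein.
    """

    def __init__(self, values: pd.DataFrame, meta, layer: str,
                 gene_lengths: pd.Series | None = None):
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        if not isinstance(meta, pd.DataFrame):
            meta = _meta_frame(meta)
        missing = [s for s in values.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples missing from metadata: {missing}")
        meta = meta.loc[[s for s in meta.index if s in set(values.columns)]].copy()
        meta["layer"] = layer
        values = values.loc[:, meta.index]
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups}")
        arr = values.to_numpy(dtype=float)
        if np.any(arr < 0):
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative value at gene {values.index[g]!r}, sample {values.columns[s]!r}")
        if meta["layer"].nunique() != 1:
            raise ValueError("all samples of a matrix must share one layer")
        if gene_lengths is not None:
            gene_lengths = gene_lengths.reindex(values.index)
        self.values = values
        self.meta = meta
        self.layer = layer
        self.gene_lengths = gene_lengths

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"<ExpressionMatrix layer={self.layer} genes={self.n_genes} "
                f"samples={self.n_samples}>")

    # -- selection -----------------------------------------------------------
    def sample_ids(self, compartment: str | None = None,
                   age_group: str | None = None,
                   replicate: int | None = None) -> list[str]:
        """Sample IDs matching the given metadata criteria."""
        m = self.meta
        mask = pd.Series(True, index=m.index)
        if compartment is not None:
            mask &= m["compartment"] == compartment
        if age_group is not None:
            mask &= m["age_group"] == age_group
        if replicate is not None:
            mask &= m["replicate"] == replicate
        return m.index[mask].tolist()

    def select(self, samples: Sequence[str] | None = None, **criteria) -> "ExpressionMatrix":
        """Subset to the given sample IDs (or metadata criteria)."""
        if samples is None:
            samples = self.sample_ids(**criteria)
        missing = [s for s in samples if s not in self.meta.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return ExpressionMatrix(self.values[list(samples)], self.meta.loc[list(samples)],
                                self.layer, self.gene_lengths)

    def concat(self, other: "ExpressionMatrix") -> "ExpressionMatrix":
        """Column-concatenate two matrices of the same layer (shared genes)."""
        if other.layer != self.layer:
            raise ValueError(f"cannot concat layers {self.layer!r} and {other.layer!r}")
        shared = self.genes.intersection(other.genes)
        overlap = set(self.samples) & set(other.samples)
        if overlap:
            raise ValueError(f"duplicate sample IDs across matrices: {sorted(overlap)}")
        values = pd.concat([self.values.loc[shared], other.values.loc[shared]], axis=1)
        meta = pd.concat([self.meta, other.meta])
        lengths = self.gene_lengths.loc[shared] if self.gene_lengths is not None else None
        return ExpressionMatrix(values, meta, self.layer, lengths)

    # -- I/O -----------------------------------------------------------------
    def write(self, values_path, meta_path, lengths_path=None) -> None:
        write_expression_table(self, values_path, meta_path, lengths_path)


def _collapse_duplicates(values: pd.DataFrame, layer: str) -> pd.DataFrame:
    """Collapse duplicated gene IDs: sum for counts, max for intensities."""
    if not values.index.has_duplicates:
        return values
    if layer in COUNT_LAYERS:
        return values.groupby(level=0, sort=False).sum()
    return values.groupby(level=0, sort=False).max()


def read_expression_table(values_path, meta_path, layer: str,
                          lengths_path=None) -> ExpressionMatrix:
    """Read a gene x sample TSV plus its sample-metadata TSV.

    The values table has gene IDs in the first column and sample IDs in the
    header; duplicated gene IDs are collapsed (summed for count layers,
    maximum for intensities). Samples are reordered to metadata order; a
    sample present in the values header but absent from the metadata is an
    error naming that sample.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    unknown = [s for s in values.columns if s not in meta.index]
    if unknown:
        raise ValueError(f"sample(s) {unknown} in {values_path} missing from metadata {meta_path}")
    if "age_numeric" not in meta.columns and "age_group" in meta.columns:
        meta["age_numeric"] = meta["age_group"].map(AGE_DAYS)
    values = _collapse_duplicates(values, layer)
    order = [s for s in meta.index if s in set(values.columns)]
    values = values[order]
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = lt.iloc[:, 0].astype(float)
        lengths.index = lengths.index.astype(str)
    return ExpressionMatrix(values, meta.loc[order], layer, lengths)


def write_expression_table(matrix: ExpressionMatrix, values_path, meta_path,
                           lengths_path=None) -> None:
    """Write an ExpressionMatrix back to TSV (round-trips bit-exactly)."""
    matrix.values.rename_axis("gene_id").to_csv(values_path, sep="\t")
    matrix.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")
    if lengths_path is not None and matrix.gene_lengths is not None:
        matrix.gene_lengths.rename("length").rename_axis("gene_id").to_csv(
            lengths_path, sep="\t")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets filtered to an analysis universe.

    Sets retain only members present in the universe; sets smaller than
    ``min_size`` (default 5) after intersection are dropped.
    """

    sets: dict[str, list[str]]
    min_size: int = 5

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def filtered(self, universe: Sequence[str], min_size: int | None = None) -> "GeneSetCollection":
        """Intersect with a universe and drop undersized sets (idempotent)."""
        if min_size is None:
            min_size = self.min_size
        uni = set(universe)
        kept = {}
        for name, members in self.sets.items():
            inter = [g for g in dict.fromkeys(members) if g in uni]
            if len(inter) >= min_size:
                kept[name] = inter
        return GeneSetCollection(kept, min_size)


def read_gene_sets(path, universe: Sequence[str] | None = None,
                   min_size: int = 5) -> GeneSetCollection:
    """Read a GMT file (name, description, members... per tab-separated line).

    Duplicate members within a set are counted once; duplicate set names are
    an error. If ``universe`` is given, sets are intersected with it and sets
    below ``min_size`` are dropped.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty GMT file: {path}")
    for ln in lines:
        parts = ln.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need name, description, members): {ln!r}")
        name = parts[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r} in {path}")
        sets[name] = list(dict.fromkeys(p for p in parts[2:] if p))
    coll = GeneSetCollection(sets, min_size)
    if universe is not None:
        coll = coll.filtered(universe, min_size)
    return coll


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def write_manifest(path, **entries) -> None:
    """Write a JSON run manifest (config hash, seed, versions, ...)."""
    Path(path).write_text(json.dumps(entries, indent=2, sort_keys=True, default=str))
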