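"""Expression matrices, per-gene observations and within-species variance.

The study design this package targets: a handful of species on a known
time-calibrated phylogeny, several biological replicates per species, and a
genes x samples matrix of FPKM expression values analysed on the log2 scale.
A gene enters the analysis only if it is expressed (FPKM > 0) in every sample
of every species, so the log2 transform needs no pseudocount.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import Phylogeny

__all__ = [
    "ExpressionDataset",
    "GeneObservations",
    "load_expression_table",
    "load_species_map",
    "within_species_variance",
    "variance_correlation_matrix",
]

log = logging.getLogger(__name__)


@dataclass
class GeneObservations:
    """Replicate log2 FPKM values for one gene, grouped by species."""

    gene: str
    values: dict[str, np.ndarray]  # species -> replicate vector

    def __post_init__(self) -> None:
        self.values = {sp: np.asarray(v, dtype=float)
                       for sp, v in self.values.items()}
        for sp, v in self.values.items():
            if v.ndim != 1 or len(v) < 1:
                raise ValueError(
                    f"gene {self.gene}: species {sp} has no replicates"
                )

    @property
    def species(self) -> list[str]:
        return sorted(self.values)

    def counts(self) -> dict[str, int]:
        return {sp: len(v) for sp, v in self.values.items()}


@dataclass
class ExpressionDataset:
    """A genes x samples matrix of log2 FPKM values plus a species map.

    ``matrix`` is indexed by gene id with one column per sample;
    ``species_of`` maps every sample id to its species.  Every species must
    contribute at least two samples so within-species variance is estimable.
    """

    matrix: pd.DataFrame
    species_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.matrix.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")
        missing = [s for s in self.matrix.columns if s not in self.species_of]
        if missing:
            raise ValueError(f"samples without species assignment: {missing}")
        if self.matrix.isna().any().any():
            raise ValueError("missing values in expression matrix")
        counts: dict[str, int] = {}
        for s in self.matrix.columns:
            counts[self.species_of[s]] = counts.get(self.species_of[s], 0) + 1
        bad = [sp for sp, c in counts.items() if c < 2]
        if bad:
            raise ValueError(f"species with fewer than 2 samples: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def species(self) -> list[str]:
        return sorted({self.species_of[s] for s in self.matrix.columns})

    def samples_of(self, species: str) -> list[str]:
        return [s for s in self.matrix.columns
                if self.species_of[s] == species]

    def gene(self, gene_id: str) -> GeneObservations:
        row = self.matrix.loc[gene_id]
        values = {sp: row[self.samples_of(sp)].to_numpy(dtype=float)
                  for sp in self.species}
        return GeneObservations(gene=gene_id, values=values)

    def check_against_tree(self, tree: Phylogeny) -> None:
        if set(self.species) != set(tree.tips):
            raise ValueError(
                f"dataset species {self.species} != tree tips {tree.tips}"
            )

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t", index_label="gene")


def load_species_map(path) -> dict[str, str]:
    """Read a two-column TSV (sample id, species) into a dict."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("species map needs two columns: sample, species")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_expression_table(path, species_map: dict[str, str] | str,
                          input_scale: str = "fpkm") -> ExpressionDataset:
    """Load a genes x samples TSV into an :class:`ExpressionDataset`.

    ``input_scale="fpkm"`` (the default) expects raw FPKM values: genes with
    any value <= 0 are dropped under the expressed-in-every-sample rule and
    the survivors are log2-transformed.  ``input_scale="log2"`` takes the
    matrix as already log2-transformed and applies no filter.

    Parameters
    ----------
    species_map
        Either a ``{sample: species}`` dict or a path to a two-column TSV.
    """
    if not isinstance(species_map, dict):
        species_map = load_species_map(species_map)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    missing = [s for s in df.columns if s not in species_map]
    if missing:
        raise ValueError(f"samples without species assignment: {missing}")
    for col in df.columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"non-numeric expression value at gene {bad[0]!r}, "
                f"sample {col!r}"
            )
    df = df.astype(float)
    if input_scale == "fpkm":
        expressed = (df > 0).all(axis=1)
        n_drop = int((~expressed).sum())
        if n_drop:
            log.info("dropped %d genes not expressed in every sample", n_drop)
        df = np.log2(df.loc[expressed])
    elif input_scale != "log2":
        raise ValueError("input_scale must be 'fpkm' or 'log2'")
    used = {s: species_map[s] for s in df.columns}
    return ExpressionDataset(matrix=df, species_of=used)


def within_species_variance(gene: GeneObservations) -> dict[str, float]:
    """Sample variance (n-1 denominator) of each species' replicates."""
    for sp, v in gene.values.items():
        if len(v) < 2:
            raise ValueError(
                f"gene {gene.gene}: species {sp} needs >=2 replicates "
                "for a variance estimate")
    return {sp: float(np.var(v, ddof=1)) for sp, v in gene.values.items()}


def variance_correlation_matrix(dataset: ExpressionDataset) -> pd.DataFrame:
    """Species x species Pearson correlation of per-gene variance vectors.

    For each species, the per-gene within-species variances form a vector
    over genes; the returned matrix holds the pairwise Pearson correlations
    of those vectors.  A species whose variance vector is constant yields NaN
    correlations (undefined, reported as missing rather than zero).
    """
    if len(dataset.genes) < 3:
        raise ValueError("need at least 3 genes to correlate variances")
    species = dataset.species
    cols = {}
    for sp in species:
        sub = dataset.matrix[dataset.samples_of(sp)].to_numpy(dtype=float)
        cols[sp] = sub.var(axis=1, ddof=1)
    var_df = pd.DataFrame(cols, index=dataset.genes)
    corr = var_df.corr(method="pearson")
    # pandas leaves the diagonal at 1 even for constant columns; force NaN
    for sp in species:
        if np.isclose(var_df[sp].var(), 0.0):
            corr.loc[sp, :] = np.nan
            corr.loc[:, sp] = np.nan
    return corr
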