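"""Core data containers shared across the pipeline.

The common currency is the gene × sample expression matrix, carried together
with per-sample covariates and a unit tag so that stages can refuse inputs in
the wrong state (e.g. re-normalizing log2-CPM values). Genotypes travel with
variant positions and a gene TSS map because the cis-eQTL window and the
causal-orientation pass both need genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "GenotypeData",
    "CellTypeResidual",
    "VarianceFractions",
    "TruthBundle",
    "CausalNetwork",
]

UNITS = ("counts", "log2cpm", "residual")


@dataclass
class ExpressionMatrix:
    """Gene × sample expression values plus sample metadata.

    Parameters
    ----------
    values : DataFrame
        Genes in rows, samples in columns.
    sample_metadata : DataFrame
        Samples in rows, covariates in columns. Index must cover the columns
        of ``values``.
    unit : str
        One of ``counts``, ``log2cpm`` or ``residual``.
    """

    values: pd.DataFrame
    sample_metadata: pd.DataFrame = None
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if self.sample_metadata is None:
            self.sample_metadata = pd.DataFrame(index=self.values.columns)
        missing = self.values.columns.difference(self.sample_metadata.index)
        if len(missing):
            raise ValueError(f"samples without metadata: {list(missing[:5])}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        samples = pd.Index(samples)
        return ExpressionMatrix(
            self.values.loc[:, samples],
            self.sample_metadata.loc[samples],
            unit=self.unit,
        )


@dataclass
class GenotypeData:
    """Variant × subject allele dosages with genomic coordinates.

    ``dosages`` holds values in [0, 2]; ``variant_positions`` maps each
    variant to (chromosome, 1-based position); ``gene_annotation`` maps genes
    to (chromosome, 1-based TSS, strand) for the cis-window arithmetic.
    """

    dosages: pd.DataFrame
    variant_positions: pd.DataFrame  # index=variant, columns chrom,pos
    gene_annotation: pd.DataFrame = None  # index=gene, columns chrom,tss,strand

    def __post_init__(self) -> None:
        vals = self.dosages.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        missing = self.dosages.index.difference(self.variant_positions.index)
        if len(missing):
            raise ValueError(f"variants without positions: {list(missing[:5])}")
        if len(self.variant_positions) and (self.variant_positions["pos"] <= 0).any():
            raise ValueError("variant positions must be positive 1-based integers")

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns


@dataclass
class CellTypeResidual:
    """Deconvolved cell-type-specific expression residuals.

    The stored matrix is, per gene, the OLS residual of the normalized bulk
    expression on covariates plus all cell-type markers, with the fitted
    effect of ``marker_gene`` added back. Markers themselves are excluded
    from the rows.
    """

    values: pd.DataFrame
    cell_type: str
    marker_gene: str
    adjusted_covariates: list
    fit_coefficients: pd.DataFrame = None  # genes × regressors

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def as_expression(self, sample_metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
        return ExpressionMatrix(self.values, sample_metadata, unit="residual")


@dataclass
class VarianceFractions:
    """Per-gene fraction of expression variance attributed to each covariate.

    ``fractions`` has genes in rows and covariates plus a ``residual`` column;
    each row is non-negative and sums to 1.
    """

    fractions: pd.DataFrame
    method: str = "partial_r2"

    def __post_init__(self) -> None:
        if "residual" not in self.fractions.columns:
            raise ValueError("fractions must include a 'residual' column")


@dataclass
class TruthBundle:
    """Ground truth recorded by the synthetic cohort generator."""

    dag: nx.DiGraph
    de_genes: dict            # cell type -> list of genes with case effects
    eqtl_map: dict            # gene -> (variant id, effect)
    cell_fractions: pd.DataFrame  # subjects × cell types, rows on the simplex
    marker_genes: dict        # cell type -> marker gene
    module_labels: dict = field(default_factory=dict)
    key_regulators: list = field(default_factory=list)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise ValueError("truth DAG contains a cycle")
        rowsums = self.cell_fractions.sum(axis=1).to_numpy()
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("cell fraction rows must sum to 1")
        markers = list(self.marker_genes.values())
        if len(markers) != len(set(markers)):
            raise ValueError("each marker gene must belong to exactly one cell type")


@dataclass
class CausalNetwork:
    """A directed gene network with per-edge posterior probabilities.

    ``graph`` is a networkx DiGraph whose edges carry a ``posterior``
    attribute in [0, 1]. ``metadata`` records provenance: dataset tag,
    gene-set tag (seed/expanded), model type (bayes/predictive) and the
    posterior cut-off applied. Thresholded consensus graphs may contain
    cycles; ``is_acyclic`` records whether this one does not.
    """

    graph: nx.DiGraph
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            p = d.get("posterior", 1.0)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"edge {u}->{v} posterior {p} outside [0, 1]")

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.graph)

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, "posterior": d.get("posterior", np.nan)}
            for u, v, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["source", "target", "posterior"])
        for key, val in self.metadata.items():
            if np.isscalar(val):
                df[key] = val
        return df
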