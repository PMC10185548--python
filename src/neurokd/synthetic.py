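"""Synthetic brain-cohort generator.

Emulates the statistical structure of a postmortem bulk RNA-seq case/control
cohort in which the measured bulk signal is a convolution of several CNS cell
types: per-subject cell fractions on a simplex, one dominant marker gene per
cell type, case effects planted in a designated "neuron" cell type, cis-acting
genotype effects, nuisance covariates (batch, sex, age, RIN) and a
linear-Gaussian causal DAG among genes. Everything planted is recorded in a
:class:`~neurokd.containers.TruthBundle` so downstream stages can be tested
for parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import substream
from .containers import ExpressionMatrix, GenotypeData, TruthBundle

__all__ = [
    "CohortConfig",
    "simulate_genotypes",
    "simulate_truth_dag",
    "simulate_bulk_cohort",
    "simulate_instrumented_sem",
    "write_cohort",
]

#: fixed spacing between synthetic variants (one synthetic chromosome);
#: 10 kb keeps the 1 Mb cis window meaningful at toy scale
VARIANT_SPACING = 10_000
CHROM = "chr1"

DEFAULT_COVARIATES = [
    ("batch", "categorical", 0.5),
    ("sex", "categorical", 0.3),
    ("age", "continuous", 0.3),
    ("rin", "continuous", 0.3),
]

DEFAULT_CELL_TYPES = ["neuron", "microglia", "astrocyte", "endothelial", "oligodendrocyte"]

#: neuron-heavy Dirichlet base proportions mirroring cortex composition
DEFAULT_FRACTION_PROPS = {
    "neuron": 0.45,
    "microglia": 0.10,
    "astrocyte": 0.20,
    "endothelial": 0.05,
    "oligodendrocyte": 0.20,
}


@dataclass
class CohortConfig:
    """Simulation knobs for one synthetic cohort.

    The defaults describe a small but realistic two-arm postmortem cohort:
    roughly balanced cases and controls, five CNS cell types with one marker
    each, a sparse causal DAG, moderate planted case and cis-eQTL effects and
    the usual nuisance covariates.
    """

    n_subjects: int = 400
    n_cases: int = 200
    n_genes: int = 200
    n_cell_types: int = 5
    n_variants: int = 120
    maf_range: tuple = (0.1, 0.5)
    dag_edge_density: float = 1.5
    de_fraction: float = 0.25
    de_effect_size: float = 1.0
    eqtl_fraction: float = 0.25
    eqtl_effect_size: float = 0.8
    covariate_spec: list = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    noise_sd: float = 0.5
    seed: int = 0
    #: Dirichlet concentration scaling; larger = less fraction variability
    fraction_concentration: float = 30.0
    #: number of planted high-out-degree regulators feeding the DE genes
    n_key_regulators: int = 1
    #: fraction of DE genes wired as children of each key regulator
    regulator_fanout: float = 0.8
    marker_level: float = 10.0

    def __post_init__(self) -> None:
        if self.n_cases > self.n_subjects:
            raise ValueError("n_cases cannot exceed n_subjects")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for frac, name in [
            (self.de_fraction, "de_fraction"),
            (self.eqtl_fraction, "eqtl_fraction"),
            (self.regulator_fanout, "regulator_fanout"),
        ]:
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dag_edge_density < 0:
            raise ValueError("dag_edge_density must be non-negative")
        if self.n_cell_types < 1:
            raise ValueError("need at least one cell type")

    @property
    def cell_types(self) -> list:
        if self.n_cell_types <= len(DEFAULT_CELL_TYPES):
            return DEFAULT_CELL_TYPES[: self.n_cell_types]
        extra = [f"celltype{i}" for i in range(len(DEFAULT_CELL_TYPES), self.n_cell_types)]
        return DEFAULT_CELL_TYPES + extra


def simulate_genotypes(
    n_variants: int,
    n_subjects: int,
    maf_range: tuple = (0.1, 0.5),
    seed: int = 0,
    sample_ids: Sequence[str] | None = None,
) -> GenotypeData:
    """Simulate biallelic dosages under Hardy–Weinberg equilibrium.

    Each variant receives a minor-allele frequency uniform in ``maf_range``;
    dosages are the sum of two Bernoulli(MAF) draws. Variants are laid out on
    one synthetic chromosome at fixed 10 kb spacing.
    """
    if n_variants < 1 or n_subjects < 1:
        raise ValueError("n_variants and n_subjects must be >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = substream(seed, "genotypes")
    mafs = rng.uniform(lo, hi, size=n_variants)
    dosages = (
        (rng.random((n_variants, n_subjects)) < mafs[:, None]).astype(int)
        + (rng.random((n_variants, n_subjects)) < mafs[:, None]).astype(int)
    )
    variant_ids = [f"rs{i}" for i in range(n_variants)]
    if sample_ids is None:
        sample_ids = [f"S{i}" for i in range(n_subjects)]
    positions = pd.DataFrame(
        {"chrom": CHROM, "pos": VARIANT_SPACING * (np.arange(n_variants) + 1)},
        index=pd.Index(variant_ids, name="variant"),
    )
    dos = pd.DataFrame(dosages, index=positions.index, columns=list(sample_ids))
    return GenotypeData(dosages=dos.astype(float), variant_positions=positions)


def simulate_truth_dag(
    n_genes: int,
    edge_density: float,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    weight_range: tuple = (0.4, 0.9),
) -> nx.DiGraph:
    """Sample a random weighted DAG over ``n_genes`` genes.

    A random topological order is drawn; each ordered pair is admitted as an
    edge with probability ``edge_density / (n_genes - 1)`` so the expected
    parent count per gene equals ``edge_density``. Weights are
    signed-magnitude: a uniform magnitude in ``weight_range`` with a random
    sign.
    """
    if n_genes < 2:
        raise ValueError("need at least 2 genes")
    rng = substream(seed, "dag")
    if gene_ids is None:
        gene_ids = [f"G{i}" for i in range(n_genes)]
    gene_ids = list(gene_ids)
    order = rng.permutation(n_genes)
    p = min(1.0, edge_density / (n_genes - 1))
    dag = nx.DiGraph()
    dag.add_nodes_from(gene_ids)
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < p:
                w = rng.uniform(*weight_range) * rng.choice([-1.0, 1.0])
                dag.add_edge(gene_ids[order[i]], gene_ids[order[j]], weight=w)
    assert nx.is_directed_acyclic_graph(dag)
    return dag


def _simulate_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    subjects = [f"S{i}" for i in range(config.n_subjects)]
    dx = ["case"] * config.n_cases + ["control"] * (config.n_subjects - config.n_cases)
    cov = pd.DataFrame(index=pd.Index(subjects, name="sample"))
    cov["diagnosis"] = dx
    for name, kind, _ in config.covariate_spec:
        if kind == "categorical":
            n_levels = 3 if name == "batch" else 2
            cov[name] = [f"{name}{k}" for k in rng.integers(0, n_levels, config.n_subjects)]
        else:
            cov[name] = rng.normal(0.0, 1.0, config.n_subjects)
    return cov


def _covariate_effect_matrix(
    config: CohortConfig, cov: pd.DataFrame, rng: np.random.Generator, n_genes: int
) -> np.ndarray:
    """Per-gene additive nuisance effects, genes × subjects."""
    total = np.zeros((n_genes, len(cov)))
    for name, kind, effect in config.covariate_spec:
        if effect == 0:
            continue
        if kind == "categorical":
            levels = pd.Categorical(cov[name]).codes.astype(float)
            levels -= levels.mean()
            vec = levels
        else:
            vec = cov[name].to_numpy(dtype=float)
        loadings = rng.normal(0.0, effect, n_genes)
        total += loadings[:, None] * vec[None, :]
    return total


def simulate_bulk_cohort(config: CohortConfig):
    """Generate one convolved bulk cohort plus its ground truth.

    Returns ``(bulk, genotypes, covariates, truth)``. Per cell type, gene
    expression follows the linear-Gaussian structural model on a shared truth
    DAG (independent noise realizations per cell type); cis-eQTL effects and
    case effects are planted in the designated neuron cell type only, so that
    deconvolution — not the raw bulk — is what exposes them. The bulk value
    is the fraction-weighted mixture of cell-type expression plus nuisance
    covariate effects and measurement noise. Marker genes are expressed at a
    high level in exactly one cell type and are excluded from the DAG and
    from DE effects.
    """
    cfg = config
    rng = substream(cfg.seed, "cohort")
    cell_types = cfg.cell_types
    target_ct = cell_types[0]

    marker_genes = {ct: f"MARKER_{ct.upper()}" for ct in cell_types}
    program_genes = [f"G{i}" for i in range(cfg.n_genes - len(cell_types))]
    all_genes = program_genes + list(marker_genes.values())

    dag = simulate_truth_dag(
        max(2, len(program_genes)), cfg.dag_edge_density, seed=cfg.seed, gene_ids=program_genes
    )

    # planted DE genes (neuron only by default)
    n_de = int(round(cfg.de_fraction * len(program_genes)))
    de_pool = rng.permutation(program_genes)
    de_genes = sorted(de_pool[:n_de].tolist())

    # planted key regulators: roots wired into a large share of the DE genes
    key_regulators = []
    non_de = [g for g in program_genes if g not in set(de_genes)]
    for r in range(min(cfg.n_key_regulators, len(non_de))):
        reg = non_de[r]
        key_regulators.append(reg)
        # make the regulator a root
        for parent in list(dag.predecessors(reg)):
            dag.remove_edge(parent, reg)
        n_child = int(np.ceil(cfg.regulator_fanout * len(de_genes)))
        for child in de_genes[:n_child]:
            if not nx.has_path(dag, child, reg):  # preserve acyclicity
                w = rng.uniform(0.5, 0.9) * rng.choice([-1.0, 1.0])
                dag.add_edge(reg, child, weight=w)

    genotypes = simulate_genotypes(
        cfg.n_variants, cfg.n_subjects, cfg.maf_range, seed=cfg.seed
    )
    subjects = list(genotypes.sample_ids)

    # gene annotation: program genes placed near variants on the one chromosome
    tss = {}
    var_pos = genotypes.variant_positions
    for i, g in enumerate(all_genes):
        tss[g] = VARIANT_SPACING * (i + 1) + VARIANT_SPACING // 2
    annotation = pd.DataFrame(
        {"chrom": CHROM, "tss": [tss[g] for g in all_genes], "strand": "+"},
        index=pd.Index(all_genes, name="gene"),
    )
    genotypes.gene_annotation = annotation

    # planted cis-eQTLs: each selected gene gets its nearest variant
    n_eqtl = int(round(cfg.eqtl_fraction * len(program_genes)))
    eqtl_pool = [g for g in program_genes if g not in set(key_regulators)]
    eqtl_genes = sorted(rng.permutation(eqtl_pool)[:n_eqtl].tolist())
    eqtl_map = {}
    pos_arr = var_pos["pos"].to_numpy()
    used = set()
    for g in eqtl_genes:
        order = np.argsort(np.abs(pos_arr - tss[g]))
        vi = next((int(i) for i in order if int(i) not in used), None)
        if vi is None:
            break  # more eQTL genes than variants
        used.add(vi)
        eqtl_map[g] = (var_pos.index[vi], cfg.eqtl_effect_size)

    cov = _simulate_covariates(cfg, substream(cfg.seed, "covariates"))
    cov = cov.loc[subjects] if list(cov.index) != subjects else cov
    cov.index = pd.Index(subjects, name="sample")
    is_case = (cov["diagnosis"] == "case").to_numpy()

    # cell fractions on the simplex, neuron-heavy
    props = np.array(
        [DEFAULT_FRACTION_PROPS.get(ct, 0.1) for ct in cell_types], dtype=float
    )
    props /= props.sum()
    frac_rng = substream(cfg.seed, "fractions")
    fractions = frac_rng.dirichlet(cfg.fraction_concentration * props, size=cfg.n_subjects)
    cell_fractions = pd.DataFrame(fractions, index=cov.index, columns=cell_types)

    # per-cell-type structural expression
    topo = list(nx.topological_sort(dag))
    dose = genotypes.dosages
    expr_rng = substream(cfg.seed, "expression")
    celltype_expr = {}
    for ct in cell_types:
        mat = pd.DataFrame(0.0, index=pd.Index(all_genes, name="gene"), columns=cov.index)
        for g in topo:
            val = expr_rng.normal(0.0, 1.0, cfg.n_subjects)
            for p in dag.predecessors(g):
                val += dag.edges[p, g]["weight"] * mat.loc[p].to_numpy()
            if ct == target_ct:
                if g in eqtl_map:
                    vid, beta = eqtl_map[g]
                    val += beta * dose.loc[vid].to_numpy()
                if g in set(de_genes):
                    val += cfg.de_effect_size * is_case
            mat.loc[g] = val
        for mct, mg in marker_genes.items():
            base = expr_rng.normal(0.0, 0.2, cfg.n_subjects)
            mat.loc[mg] = base + (cfg.marker_level if mct == ct else 0.0)
        celltype_expr[ct] = mat

    # convolve
    bulk_vals = np.zeros((len(all_genes), cfg.n_subjects))
    for j, ct in enumerate(cell_types):
        bulk_vals += fractions[:, j][None, :] * celltype_expr[ct].to_numpy()
    noise_rng = substream(cfg.seed, "noise")
    bulk_vals += _covariate_effect_matrix(cfg, cov, substream(cfg.seed, "cov_effects"), len(all_genes))
    bulk_vals += noise_rng.normal(0.0, cfg.noise_sd, bulk_vals.shape)

    bulk = ExpressionMatrix(
        pd.DataFrame(bulk_vals, index=pd.Index(all_genes, name="gene"), columns=cov.index),
        sample_metadata=cov,
        unit="log2cpm",
    )

    truth = TruthBundle(
        dag=dag,
        de_genes={target_ct: de_genes},
        eqtl_map=eqtl_map,
        cell_fractions=cell_fractions,
        marker_genes=marker_genes,
        key_regulators=key_regulators,
    )
    truth.validate()
    truth.celltype_expression = celltype_expr  # kept for recovery tests
    return bulk, genotypes, cov, truth


def simulate_instrumented_sem(
    n_genes: int = 30,
    n_subjects: int = 300,
    edge_density: float = 1.5,
    maf: float = 0.3,
    instrument_effect: float = 0.8,
    seed: int = 0,
):
    """Linear-Gaussian SEM with cis instruments at its source genes.

    Benchmark generator for causal-network recovery. Genes follow the
    structural model on a random DAG; every source gene (no parents) carries
    a cis variant with a per-allele effect of ``instrument_effect`` SD. Each
    gene sits next to exactly one variant on the synthetic chromosome, so a
    cis scan with a window below the 10 kb variant spacing tests only the
    gene's own variant. Placing instruments at sources reproduces the regime
    the eQTL structure prior encodes — genetically perturbed genes acting as
    causal sources.

    Returns ``(expr, genotypes, dag, instrument_map)``.
    """
    rng = substream(seed, "instrumented_sem")
    dag = simulate_truth_dag(n_genes, edge_density, seed=seed)
    genes = list(dag.nodes)
    genotypes = simulate_genotypes(n_genes, n_subjects, (maf, maf), seed=seed)
    gidx = {g: i for i, g in enumerate(genes)}
    annotation = pd.DataFrame(
        {
            "chrom": CHROM,
            "tss": [VARIANT_SPACING * (gidx[g] + 1) + 100 for g in genes],
            "strand": "+",
        },
        index=pd.Index(genes, name="gene"),
    )
    genotypes.gene_annotation = annotation
    roots = [g for g in genes if dag.in_degree(g) == 0]
    instrument_map = {g: genotypes.variant_ids[gidx[g]] for g in roots}

    data = {}
    for g in nx.topological_sort(dag):
        val = rng.normal(0.0, 1.0, n_subjects)
        for p in dag.predecessors(g):
            val = val + dag.edges[p, g]["weight"] * data[p]
        if g in instrument_map:
            val = val + instrument_effect * genotypes.dosages.loc[instrument_map[g]].to_numpy()
        data[g] = val
    expr = pd.DataFrame(data).T
    expr.columns = genotypes.dosages.columns
    expr.index.name = "gene"
    return expr, genotypes, dag, instrument_map


def write_cohort(outputs, directory) -> dict:
    """Write a simulated cohort to ``directory`` as plain-text files.

    Expression and covariates as TSV, genotypes as both a dosage TSV and a
    minimal VCF, gene annotation as TSV, and the truth bundle as JSON. The
    files round-trip losslessly through :mod:`neurokd.io`.
    """
    from . import io as nio  # local import to avoid a cycle
    import os

    bulk, genotypes, cov, truth = outputs
    os.makedirs(directory, exist_ok=True)
    paths = {
        "expression": os.path.join(directory, "expression.tsv"),
        "covariates": os.path.join(directory, "covariates.tsv"),
        "dosages": os.path.join(directory, "dosages.tsv"),
        "vcf": os.path.join(directory, "genotypes.vcf"),
        "annotation": os.path.join(directory, "gene_annotation.tsv"),
        "truth": os.path.join(directory, "truth.json"),
    }
    nio.write_expression_tsv(bulk, paths["expression"])
    nio.write_covariates_tsv(cov, paths["covariates"])
    nio.write_dosage_tsv(genotypes, paths["dosages"])
    nio.write_vcf(genotypes, paths["vcf"])
    nio.write_gene_annotation_tsv(genotypes.gene_annotation, paths["annotation"])
    nio.write_truth_json(truth, paths["truth"])
    return paths
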