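"""End-to-end orchestration of the neuron-specific network pipeline.

Stages run in dependency order: simulate (or ingest) → deconvolve → DE +
cis-eQTL → co-expression modules and seeding-set selection → pathway
expansion → causal network ensembles (per gene set × model type × cut-off)
→ key driver analysis → impact/robustness scoring and prioritization. A
manifest JSON records the configuration, seeds, per-stage result sizes and
content hashes of written files. The cross-cohort replication report
reproduces the overlap summaries used to cross-validate two cohorts at each
stage.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from ._rng import child_seed
from . import io as nio
from .causal import GaussianNetworkModel, LearnConfig, StructurePrior
from .coexpression import adjacency, detect_modules, select_ad_modules, topological_overlap
from .containers import CausalNetwork
from .deconvolution import compute_celltype_residual
from .keydrivers import KdaConfig, aggregate_key_drivers, kda, rank_and_prioritize
from .pathfinder import MixedGraph, expand_seed_genes
from .stats import differential_expression, map_cis_eqtl, overlap_from_counts
from .synthetic import CohortConfig, simulate_bulk_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "replication_report"]

_KNOWN_KEYS = {
    "seed", "out_dir", "dataset", "cohort", "deconvolution", "de", "eqtl",
    "coexpression", "network", "kda", "prioritize", "skip_eqtl", "pathway_graph",
}


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    dataset: str = "synthetic"
    cohort: dict = field(default_factory=dict)
    deconvolution: dict = field(default_factory=dict)
    eqtl: dict = field(default_factory=lambda: {"window": 1_000_000, "fdr": 0.01})
    coexpression: dict = field(default_factory=lambda: {"power": 6.5, "min_size": 30})
    network: dict = field(default_factory=lambda: {
        "n_bootstrap": 20, "max_parents": 3,
        "cutoffs": [0.4, 0.5], "model_types": ["bayes", "predictive"],
    })
    kda: dict = field(default_factory=lambda: {"K": 6, "fdr": 0.05})
    prioritize: dict = field(default_factory=lambda: {"top_n": 50})
    skip_eqtl: bool = False
    pathway_graph: MixedGraph | None = None

    @classmethod
    def from_dict(cls, doc: Mapping) -> "PipelineConfig":
        unknown = set(doc) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**doc)


@dataclass
class PipelineResult:
    """All stage outputs of one pipeline run."""

    config: PipelineConfig
    residual: object = None
    de_table: pd.DataFrame = None
    eqtl: object = None
    modules: object = None
    module_summary: pd.DataFrame = None
    seeding_genes: set = field(default_factory=set)
    expanded_genes: set = field(default_factory=set)
    networks: list = field(default_factory=list)
    kda_tables: list = field(default_factory=list)
    key_drivers: pd.DataFrame = None
    prioritized: pd.DataFrame = None
    truth: object = None
    manifest: dict = field(default_factory=dict)

    @property
    def de_genes(self) -> set:
        if self.de_table is None:
            return set()
        return set(self.de_table.index[self.de_table["significant"]])


def _hash_frame(frame: pd.DataFrame) -> str:
    payload = frame.to_csv().encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig | Mapping) -> PipelineResult:
    """Execute the full pipeline on a synthetic cohort.

    Every stage derives its random stream from the single top-level seed,
    so reruns with the same configuration are bit-identical.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(dict(config))
    t0 = time.time()
    manifest: dict = {"stages": {}, "seed": config.seed, "dataset": config.dataset}
    result = PipelineResult(config=config, manifest=manifest)

    def mark(stage, **info):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 3), **info}

    # --- simulate ---------------------------------------------------------
    cohort_kw = dict(config.cohort)
    cohort_kw.setdefault("seed", child_seed(config.seed, "cohort"))
    cohort_cfg = CohortConfig(**cohort_kw)
    bulk, genotypes, covariates, truth = simulate_bulk_cohort(cohort_cfg)
    result.truth = truth
    mark("simulate", n_genes=bulk.n_genes, n_subjects=bulk.n_samples)

    # --- deconvolve -------------------------------------------------------
    covariate_names = [name for name, _, _ in cohort_cfg.covariate_spec]
    markers = {ct: g for ct, g in truth.marker_genes.items()}
    target_ct = cohort_cfg.cell_types[0]
    residual = compute_celltype_residual(bulk, covariate_names, markers, target_ct,
                                         **config.deconvolution)
    result.residual = residual
    mark("deconvolve", n_genes=residual.values.shape[0], cell_type=target_ct)

    # --- DE + eQTL --------------------------------------------------------
    group = covariates["diagnosis"].map({"case": "case", "control": "control"})
    de_table = differential_expression(residual, group)
    result.de_table = de_table
    mark("de", n_significant=int(de_table["significant"].sum()))

    eqtl_res = None
    if not config.skip_eqtl:
        eqtl_res = map_cis_eqtl(residual, genotypes, **config.eqtl)
        result.eqtl = eqtl_res
        mark("eqtl", n_eqtl_genes=len(eqtl_res.eqtl_genes),
             n_pairs=len(eqtl_res.pairs))

    # --- co-expression modules on cases ----------------------------------
    case_samples = covariates.index[covariates["diagnosis"] == "case"]
    expr_cases = residual.values.loc[:, case_samples]
    # guard against numerically constant rows in the correlation
    keep = expr_cases.std(axis=1) > 1e-12
    expr_cases = expr_cases.loc[keep]
    adj = adjacency(expr_cases, power=config.coexpression.get("power", 6.5))
    tom = topological_overlap(adj)
    modules = detect_modules(
        tom,
        min_size=config.coexpression.get("min_size", 30),
        cut_height=config.coexpression.get("cut_height", 0.995),
        expr=expr_cases,
    )
    result.modules = modules
    universe = set(expr_cases.index)
    neuron_markers = set()  # marker rows are excluded from residuals
    summary, seeding = select_ad_modules(
        modules, result.de_genes, neuron_markers, universe,
        fdr=config.coexpression.get("fdr", 0.05),
    )
    fallback = False
    if not seeding:
        # cohorts far below the module-size scale yield no enriched module;
        # fall back to the full analyzed gene set (recorded in the manifest)
        # so regulators that are upstream of, but not inside, the DE
        # signature still enter the networks
        seeding = set(expr_cases.index)
        fallback = True
    result.module_summary = summary
    result.seeding_genes = seeding
    mark("coexpress", n_modules=len(modules.module_ids), n_seeding=len(seeding),
         fallback_seeding=fallback)

    # --- pathway expansion ------------------------------------------------
    if config.pathway_graph is not None:
        expanded = expand_seed_genes(config.pathway_graph, seeding,
                                     K=config.coexpression.get("pathfinder_K", 4))
        expanded &= set(residual.gene_ids) | seeding
    else:
        expanded = set(seeding)
    result.expanded_genes = expanded
    mark("expand", n_expanded=len(expanded))

    # --- causal networks --------------------------------------------------
    net_cfg = dict(config.network)
    cutoffs = net_cfg.pop("cutoffs", [0.4, 0.5])
    model_types = net_cfg.pop("model_types", ["bayes", "predictive"])
    gene_sets = {"seed": sorted(seeding)}
    if expanded != seeding:
        gene_sets["expanded"] = sorted(expanded)

    networks = []
    for tag, genes in gene_sets.items():
        genes = [g for g in genes if g in residual.gene_ids]
        expr = residual.values.loc[genes]
        prior = None
        if eqtl_res is not None:
            prior = StructurePrior(set(eqtl_res.eqtl_genes) & set(genes))
        model = GaussianNetworkModel(
            expr, prior=prior,
            genotypes=genotypes if eqtl_res is not None else None,
            eqtl=eqtl_res,
        )
        fit = model.fit(LearnConfig(seed=child_seed(config.seed, f"network:{tag}"),
                                    **net_cfg))
        for model_type in model_types:
            if model_type == "predictive" and eqtl_res is None:
                continue
            for cutoff in cutoffs:
                net = fit.network(cutoff=cutoff, model_type=model_type,
                                  metadata={"dataset": config.dataset,
                                            "gene_set": tag})
                networks.append(net)
    result.networks = networks
    mark("network", n_networks=len(networks),
         edges=[n.graph.number_of_edges() for n in networks])

    # --- KDA + prioritization --------------------------------------------
    kda_cfg = KdaConfig(**config.kda)
    targets = result.de_genes
    kda_tables = []
    for net in networks:
        try:
            kda_tables.append(kda(net, targets, kda_cfg))
        except ValueError:
            kda_tables.append(pd.DataFrame(
                columns=["p", "best_k", "downstream_size", "downstream_hits",
                         "q", "is_key_driver"]))
    result.kda_tables = kda_tables
    effectors = targets
    records = aggregate_key_drivers(networks, kda_tables, effectors)
    result.key_drivers = records
    if len(records):
        result.prioritized = rank_and_prioritize(records, **config.prioritize)
    else:
        result.prioritized = records
    significant = set()
    for table in kda_tables:
        if len(table):
            significant |= set(table.index[table["is_key_driver"]])
    mark("kda", n_key_drivers=len(records), n_significant_drivers=len(significant),
         n_prioritized=len(result.prioritized))

    # --- manifest ---------------------------------------------------------
    manifest["hashes"] = {
        "de_table": _hash_frame(de_table),
        "key_drivers": _hash_frame(records) if len(records) else "",
        "prioritized": _hash_frame(result.prioritized) if len(result.prioritized) else "",
    }
    if config.out_dir:
        os.makedirs(config.out_dir, exist_ok=True)
        de_table.to_csv(os.path.join(config.out_dir, "de_table.tsv"), sep="\t")
        records.to_csv(os.path.join(config.out_dir, "key_drivers.tsv"), sep="\t")
        result.prioritized.to_csv(
            os.path.join(config.out_dir, "prioritized.tsv"), sep="\t")
        for i, net in enumerate(networks):
            nio.write_network(net, os.path.join(config.out_dir, f"network_{i}.tsv"))
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
    return result


def replication_report(result_a: PipelineResult, result_b: PipelineResult,
                       labels=("A", "B")) -> pd.DataFrame:
    """Cross-cohort overlap summary mirroring the per-stage Venn checks.

    For each stage's significant set (DE genes, eQTL genes, seeding genes,
    key drivers), the overlap over the intersection of analyzed genes is
    reported with percentages at one decimal.
    """
    gene_universe = set(result_a.residual.gene_ids) & set(result_b.residual.gene_ids)
    if not gene_universe:
        raise ValueError(
            f"analyzed gene sets are disjoint: {len(result_a.residual.gene_ids)} vs "
            f"{len(result_b.residual.gene_ids)} genes")
    rows = []
    stages = {
        "de_genes": (result_a.de_genes, result_b.de_genes),
        "eqtl_genes": (
            set(result_a.eqtl.eqtl_genes) if result_a.eqtl is not None else set(),
            set(result_b.eqtl.eqtl_genes) if result_b.eqtl is not None else set(),
        ),
        "seeding_genes": (result_a.seeding_genes, result_b.seeding_genes),
        "key_drivers": (
            set(result_a.key_drivers.index), set(result_b.key_drivers.index),
        ),
    }
    for stage, (sa, sb) in stages.items():
        sa, sb = sa & gene_universe, sb & gene_universe
        stat = overlap_from_counts(len(sa), len(sb), len(sa & sb), len(gene_universe))
        rows.append({
            "stage": stage,
            f"n_{labels[0]}": stat.n_a, f"n_{labels[1]}": stat.n_b,
            "n_overlap": stat.n_overlap,
            f"pct_{labels[0]}": round(stat.pct_a, 1),
            f"pct_{labels[1]}": round(stat.pct_b, 1),
            "odds_ratio": stat.odds_ratio, "p": stat.p,
        })
    return pd.DataFrame(rows).set_index("stage")
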