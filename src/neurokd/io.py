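"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated with a header row and gene/sample IDs
as opaque case-sensitive strings. Genotypes travel as a minimal VCF v4.2
with a DS (dosage) FORMAT field, or as a dosage TSV plus a variant map.
Coordinates are 1-based throughout (VCF convention). Gzipped variants of the
text formats are accepted transparently.
"""

from __future__ import annotations

import gzip
import json
import os
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CausalNetwork, ExpressionMatrix, GenotypeData, TruthBundle

__all__ = [
    "read_expression_tsv", "write_expression_tsv",
    "read_covariates_tsv", "write_covariates_tsv",
    "read_dosage_tsv", "write_dosage_tsv",
    "read_vcf_dosages", "write_vcf",
    "read_gene_annotation_tsv", "write_gene_annotation_tsv",
    "read_gene_list", "write_gene_list",
    "read_gmt", "read_truth_json", "write_truth_json",
    "read_network", "write_network",
]


def _open(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_expression_tsv(path, unit: str = "counts",
                        covariates_path=None) -> ExpressionMatrix:
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index.name = "gene"
    meta = read_covariates_tsv(covariates_path) if covariates_path else None
    return ExpressionMatrix(values, meta, unit=unit)


def write_expression_tsv(matrix: ExpressionMatrix | pd.DataFrame, path) -> None:
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    values.to_csv(path, sep="\t", index_label="gene")


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_covariates_tsv(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, sep="\t", index_label="sample")


def read_dosage_tsv(path, variant_map_path=None, annotation_path=None) -> GenotypeData:
    """Dosage TSV: first columns ``variant``, ``chrom``, ``pos``, then samples."""
    frame = pd.read_csv(path, sep="\t")
    required = {"variant", "chrom", "pos"}
    if not required <= set(frame.columns):
        raise ValueError(f"{path}: dosage TSV must carry columns {sorted(required)}")
    frame = frame.set_index("variant")
    positions = frame[["chrom", "pos"]]
    dosages = frame.drop(columns=["chrom", "pos"]).astype(float)
    ann = read_gene_annotation_tsv(annotation_path) if annotation_path else None
    return GenotypeData(dosages, positions, ann)


def write_dosage_tsv(genotypes: GenotypeData, path) -> None:
    out = genotypes.variant_positions.join(genotypes.dosages)
    out.to_csv(path, sep="\t", index_label="variant")


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">
"""


def write_vcf(genotypes: GenotypeData, path) -> None:
    """Minimal VCF v4.2 with one biallelic record per variant, DS field."""
    samples = list(genotypes.sample_ids)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT")
        if samples:
            fh.write("\t" + "\t".join(samples))
        fh.write("\n")
        for v in genotypes.variant_ids:
            chrom = genotypes.variant_positions.loc[v, "chrom"]
            pos = int(genotypes.variant_positions.loc[v, "pos"])
            doses = genotypes.dosages.loc[v]
            fields = [str(chrom), str(pos), str(v), "A", "G", ".", "PASS", ".", "DS"]
            fields += [f"{d:g}" for d in doses]
            fh.write("\t".join(fields) + "\n")


def read_vcf_dosages(path, annotation_path=None) -> GenotypeData:
    """Read dosages from a VCF via cyvcf2: DS when present, else GT counts.

    Multi-allelic records are skipped (counted); missing FORMAT raises.
    """
    import logging

    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, index, positions = [], [], []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) > 1:
            n_multi += 1
            continue
        if rec.FORMAT and "DS" in rec.FORMAT:
            dose = np.asarray(rec.format("DS"), dtype=float).ravel()
        elif rec.gt_types is not None and len(rec.gt_types):
            # gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
            mapping = {0: 0.0, 1: 1.0, 2: np.nan, 3: 2.0}
            dose = np.array([mapping[t] for t in rec.gt_types])
        else:
            raise ValueError(f"{path}: record {rec.CHROM}:{rec.POS} lacks DS/GT FORMAT")
        rows.append(dose)
        index.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        positions.append((rec.CHROM, rec.POS))
    if n_multi:
        logging.getLogger(__name__).info("skipped %d multi-allelic records", n_multi)
    dosages = pd.DataFrame(rows, index=pd.Index(index, name="variant"), columns=samples)
    pos = pd.DataFrame(positions, index=dosages.index, columns=["chrom", "pos"])
    ann = read_gene_annotation_tsv(annotation_path) if annotation_path else None
    return GenotypeData(dosages, pos, ann)


def read_gene_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "tss"}
    if not required <= set(ann.columns):
        raise ValueError(f"{path}: annotation must carry columns {sorted(required)}")
    if "strand" not in ann.columns:
        ann["strand"] = "+"
    return ann.set_index("gene")


def write_gene_annotation_tsv(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene")


def read_gene_list(path) -> list:
    with _open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path) -> dict:
    """GMT pathway collection: name, description, then member genes."""
    collection: dict = {}
    n_lines = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name = parts[0]
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            collection[name] = set(g for g in parts[2:] if g)
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return collection


def write_truth_json(truth: TruthBundle, path) -> None:
    doc = {
        "dag": [
            {"source": u, "target": v, "weight": d.get("weight", 1.0)}
            for u, v, d in truth.dag.edges(data=True)
        ],
        "dag_nodes": sorted(truth.dag.nodes, key=str),
        "de_genes": {ct: sorted(g) for ct, g in truth.de_genes.items()},
        "eqtl_map": {g: {"variant": v, "effect": e} for g, (v, e) in truth.eqtl_map.items()},
        "cell_fractions": {
            "index": list(truth.cell_fractions.index),
            "columns": list(truth.cell_fractions.columns),
            "values": truth.cell_fractions.to_numpy().tolist(),
        },
        "marker_genes": dict(truth.marker_genes),
        "module_labels": dict(truth.module_labels),
        "key_regulators": list(truth.key_regulators),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_truth_json(path) -> TruthBundle:
    with _open(path) as fh:
        doc = json.load(fh)
    dag = nx.DiGraph()
    dag.add_nodes_from(doc["dag_nodes"])
    for e in doc["dag"]:
        dag.add_edge(e["source"], e["target"], weight=e["weight"])
    fractions = pd.DataFrame(
        doc["cell_fractions"]["values"],
        index=doc["cell_fractions"]["index"],
        columns=doc["cell_fractions"]["columns"],
    )
    return TruthBundle(
        dag=dag,
        de_genes={ct: list(g) for ct, g in doc["de_genes"].items()},
        eqtl_map={g: (d["variant"], d["effect"]) for g, d in doc["eqtl_map"].items()},
        cell_fractions=fractions,
        marker_genes=doc["marker_genes"],
        module_labels=doc.get("module_labels", {}),
        key_regulators=doc.get("key_regulators", []),
    )


def write_network(network: CausalNetwork, path, format: str = "tsv") -> None:
    """Write a network as edge-list TSV (lossless), SIF (drops posteriors),
    or GraphML (lossless)."""
    if format == "tsv":
        frame = network.edges_frame()
        frame.to_csv(path, sep="\t", index=False)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v in network.graph.edges():
                fh.write(f"{u}\tinteracts\t{v}\n")
    elif format == "graphml":
        g = network.graph.copy()
        g.graph.update({k: v for k, v in network.metadata.items() if np.isscalar(v)})
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_network(path, format: str = "tsv") -> CausalNetwork:
    if format == "tsv":
        frame = pd.read_csv(path, sep="\t")
        g = nx.DiGraph()
        meta = {}
        for _, row in frame.iterrows():
            g.add_edge(row["source"], row["target"], posterior=float(row["posterior"]))
        for col in frame.columns:
            if col not in ("source", "target", "posterior") and len(frame):
                vals = frame[col].unique()
                if len(vals) == 1:
                    meta[col] = vals[0]
        return CausalNetwork(g, meta)
    if format == "graphml":
        g = nx.read_graphml(path)
        return CausalNetwork(nx.DiGraph(g), dict(g.graph))
    raise ValueError(f"unknown format {format!r}")
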