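"""Post-hoc network analytics: downstream subnetworks, knockdown-signature
enrichment, consensus subnetworks, shortest paths to sink genes, and pathway
enrichment.

These are the validation analyses run after key drivers are chosen: the
downstream subnetwork of each driver is tested for enrichment of the DE
signature measured after knocking that driver down in induced neurons
(Fisher's exact test at p < 0.05, per the validation design — no FDR);
downstream edges are pooled across networks into a consensus subnetwork with
per-edge frequencies; and shortest directed paths connect drivers to
designated sink genes (e.g. REST, VGF).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CausalNetwork
from .stats import OverlapStat, fisher_overlap, two_stage_fdr

__all__ = [
    "KnockdownSignature",
    "downstream_subnetwork",
    "signature_subnetwork_enrichment",
    "consensus_subnetwork",
    "shortest_paths_to",
    "pathway_enrichment",
]


@dataclass
class KnockdownSignature:
    """DE table measured after knocking down one gene.

    q-values use the two-stage linear step-up procedure; significance is
    q < 0.05. The perturbed gene is tracked even when absent from its own
    signature table.
    """

    perturbed_gene: str
    table: pd.DataFrame  # index gene, columns effect, p (q added if missing)

    def __post_init__(self) -> None:
        if "q" not in self.table.columns:
            self.table = self.table.copy()
            self.table["q"] = two_stage_fdr(self.table["p"].to_numpy())
        if "significant" not in self.table.columns:
            self.table["significant"] = self.table["q"] < 0.05

    @property
    def significant_genes(self) -> set:
        return set(self.table.index[self.table["significant"]])

    @property
    def measured_genes(self) -> set:
        return set(self.table.index)


def downstream_subnetwork(
    network: CausalNetwork, node, max_depth: int | None = None
):
    """Directed-reachability subnetwork below ``node``.

    Returns ``(gene set, induced DiGraph)``; the root is excluded from the
    gene set but kept in the subgraph. Cycles are traversed once.
    """
    g = network.graph
    if node not in g:
        raise ValueError(f"node {node!r} not in network")
    seen = {node}
    frontier = [node]
    depth = 0
    while frontier and (max_depth is None or depth < max_depth):
        depth += 1
        nxt = []
        for u in frontier:
            for w in g.successors(u):
                if w not in seen:
                    seen.add(w)
                    nxt.append(w)
        frontier = nxt
    induced = g.subgraph(seen).copy()
    return seen - {node}, induced


def signature_subnetwork_enrichment(
    subnetwork_genes: Sequence,
    signature: KnockdownSignature,
    universe: Sequence,
    alpha: float = 0.05,
) -> OverlapStat:
    """Fisher enrichment of a knockdown DE signature in a downstream
    subnetwork; assessed at raw p < alpha (no FDR across targets)."""
    universe = set(universe)
    sub = set(subnetwork_genes) & universe
    sig = signature.significant_genes & universe
    if not sub:
        return OverlapStat(0, len(sig), 0, len(universe), 0.0, 0.0, np.nan, 1.0,
                           method="fisher[empty-subnetwork]")
    return fisher_overlap(sub, sig, universe)


def consensus_subnetwork(
    networks: Sequence[CausalNetwork], roots: Sequence, max_depth: int | None = None
) -> pd.DataFrame:
    """Pool downstream edges of the roots across networks.

    Returns an edge frame (source, target, frequency) where frequency counts
    the contributing networks containing that directed edge in the pooled
    downstream subnetwork of any root.
    """
    roots = list(roots)
    present_somewhere = any(r in net.graph for net in networks for r in roots)
    if not present_somewhere:
        raise ValueError("no root present in any network")
    counts: dict = {}
    for net in networks:
        edges = set()
        for r in roots:
            if r not in net.graph:
                continue
            _, sub = downstream_subnetwork(net, r, max_depth)
            edges |= set(sub.edges())
        for e in edges:
            counts[e] = counts.get(e, 0) + 1
    rows = [
        {"source": u, "target": v, "frequency": c}
        for (u, v), c in sorted(counts.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1])))
    ]
    frame = pd.DataFrame(rows, columns=["source", "target", "frequency"])
    frame.attrs["n_networks"] = len(networks)
    return frame


def shortest_paths_to(
    network: CausalNetwork | nx.DiGraph, sources: Sequence, sinks: Sequence
) -> dict:
    """All co-minimal directed shortest paths from each source to each sink.

    Returns {(source, sink): [path, ...]}; an unreachable pair maps to an
    empty list, and source == sink yields the zero-length path.
    """
    g = network.graph if isinstance(network, CausalNetwork) else network
    out = {}
    for s in sources:
        for t in sinks:
            key = (s, t)
            if s not in g or t not in g:
                out[key] = []
            elif s == t:
                out[key] = [[s]]
            else:
                try:
                    out[key] = [list(p) for p in nx.all_shortest_paths(g, s, t)]
                except nx.NetworkXNoPath:
                    out[key] = []
    return out


def pathway_enrichment(
    gene_set: Sequence,
    pathway_db: Mapping[str, Sequence],
    universe: Sequence,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of each pathway in ``gene_set`` over ``universe``.

    Pathways are restricted to their intersection with the universe;
    pathways disjoint from the universe are skipped. Significance at raw
    p < alpha.
    """
    import logging

    if not pathway_db:
        raise ValueError("empty pathway collection")
    universe = set(universe)
    genes = set(gene_set) & universe
    rows = []
    n_skipped = 0
    for name in sorted(pathway_db, key=str):
        members = set(pathway_db[name]) & universe
        if not members:
            n_skipped += 1
            continue
        stat = fisher_overlap(genes, members, universe)
        rows.append({
            "pathway": name, "pathway_size": len(members),
            "overlap": stat.n_overlap, "odds_ratio": stat.odds_ratio,
            "p": stat.p, "significant": stat.p < alpha,
        })
    if n_skipped:
        logging.getLogger(__name__).info(
            "skipped %d pathways disjoint from the universe", n_skipped
        )
    return pd.DataFrame(rows, columns=["pathway", "pathway_size", "overlap",
                                       "odds_ratio", "p", "significant"]).set_index("pathway")
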