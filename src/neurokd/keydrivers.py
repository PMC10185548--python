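"""Key driver analysis and driver prioritization.

A key driver is a network node whose k-step downstream neighborhood
(k = 1..K, K = 6 by default) is enriched for a target gene set — here the
AD differential-expression signature. The background for the enrichment is
the union of k-step undirected neighborhoods of the targets; the enrichment
itself uses directed reachability and an exact hypergeometric upper tail,
BH-corrected across nodes.

Drivers found across a network ensemble are ranked by an impact score
(closeness and exclusivity of regulatory paths to disease effectors) and a
robustness score (replication across datasets, gene sets and model types),
then funnelled through the rank-based selection ledger: top-50 lists per
score, the replicated intersection filtered at rank ≤ 15, top-3 unique picks
per list, curated-set members, and optional extra picks.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import CausalNetwork
from .stats import bh_fdr

__all__ = [
    "KdaConfig",
    "background_subnetwork",
    "kda",
    "impact_score",
    "robustness_score",
    "rank_and_prioritize",
    "aggregate_key_drivers",
]


@dataclass
class KdaConfig:
    K: int = 6
    neighborhood_step: int | None = None  # defaults to K
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.neighborhood_step is None:
            self.neighborhood_step = self.K


def _bfs_limited(adjacency: Mapping, start, max_depth: int) -> set:
    """Nodes within ``max_depth`` steps of ``start`` (start excluded)."""
    seen = {start}
    out = set()
    frontier = [start]
    depth = 0
    while frontier and depth < max_depth:
        depth += 1
        nxt = []
        for node in frontier:
            for nb in adjacency.get(node, ()):
                if nb not in seen:
                    seen.add(nb)
                    out.add(nb)
                    nxt.append(nb)
        frontier = nxt
    return out


def background_subnetwork(network: CausalNetwork, targets: Sequence, k: int) -> set:
    """Union of k-step undirected neighborhoods of the target genes.

    Includes the targets themselves (those present in the network)."""
    g = network.graph
    present = [t for t in targets if t in g]
    if not present:
        raise ValueError(f"no targets found in network: {sorted(set(targets))[:5]}")
    und = {n: set(g.successors(n)) | set(g.predecessors(n)) for n in g.nodes}
    result = set(present)
    for t in present:
        result |= _bfs_limited(und, t, k)
    return result


def downstream_sets(graph: nx.DiGraph, node, K: int, universe: set | None = None) -> list:
    """D_k(node) for k = 1..K: nodes reachable by directed paths of length
    ≤ k, excluding the node itself, optionally restricted to ``universe``."""
    sets = []
    seen = {node}
    frontier = [node]
    acc: set = set()
    for _ in range(K):
        nxt = []
        for n in frontier:
            for nb in graph.successors(n):
                if universe is not None and nb not in universe:
                    continue
                if nb not in seen:
                    seen.add(nb)
                    acc.add(nb)
                    nxt.append(nb)
        frontier = nxt
        sets.append(set(acc))
    return sets


def kda(network: CausalNetwork, targets: Sequence, config: KdaConfig | None = None) -> pd.DataFrame:
    """Key driver analysis of one directed network.

    For every node in the background subnetwork, the enrichment of its
    k-step directed downstream neighborhood (k = 1..K) for the target set is
    scored by a hypergeometric upper tail over the background subnetwork;
    the best p over k is kept, BH-corrected across nodes.
    """
    config = config or KdaConfig()
    targets = set(targets)
    if not targets:
        raise ValueError("empty target list")
    bg = background_subnetwork(network, targets, config.neighborhood_step)
    sub = network.graph.subgraph(bg)
    M = len(bg)
    n_targets = len(targets & bg)

    rows = []
    for v in sorted(bg, key=str):
        dsets = downstream_sets(sub, v, config.K)
        best_p, best_k, best_hits, best_size = 1.0, 0, 0, 0
        for k, dk in enumerate(dsets, start=1):
            if not dk:
                continue
            hits = len(dk & targets)
            # upper tail: P[X >= hits], X ~ Hypergeom(M-1 others, targets among them)
            n_t = n_targets - (1 if v in targets else 0)
            p = hypergeom.sf(hits - 1, M - 1, n_t, len(dk))
            if p < best_p or (p == best_p and best_k == 0):
                best_p, best_k, best_hits, best_size = p, k, hits, len(dk)
        rows.append({"gene": v, "p": best_p, "best_k": best_k,
                     "downstream_size": best_size, "downstream_hits": best_hits})
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = bh_fdr(table["p"].to_numpy())
    table["is_key_driver"] = table["q"] < config.fdr
    return table.sort_values(["q", "p"])


def impact_score(
    gene,
    networks: Sequence[CausalNetwork],
    effectors: Sequence,
) -> float:
    """Mean per-network regulatory impact of ``gene`` on the effector set.

    Within each network containing the gene, every reachable effector e
    contributes 1 / (L(e) × C(e)): L is the directed shortest-path length
    and C the product of in-degrees of the intermediate nodes along a
    shortest path chosen to minimize that product (co-regulator burden).
    Direct sole-parent regulation contributes 1. The impact is the mean of
    the per-network sums over networks containing the gene.
    """
    effectors = set(effectors)
    if not effectors:
        raise ValueError("effectors must be non-empty")
    per_network = []
    for net in networks:
        g = net.graph
        if gene not in g:
            continue
        indeg = dict(g.in_degree())
        # BFS layers + DP for min product of intermediate in-degrees
        dist = {gene: 0}
        # cost[v] = min over shortest paths of prod of in-degrees of
        # intermediate nodes on path gene -> ... -> v, v's own in-degree excluded
        cost = {gene: 1.0}
        frontier = deque([gene])
        order = []
        while frontier:
            u = frontier.popleft()
            order.append(u)
            for w in sorted(g.successors(u), key=str):
                nd = dist[u] + 1
                # cost of reaching w treating w as terminal: exclude w's in-degree
                c_terminal = cost[u] * (indeg[u] if u != gene else 1.0)
                if w not in dist:
                    dist[w] = nd
                    cost[w] = c_terminal
                    frontier.append(w)
                elif dist[w] == nd and c_terminal < cost[w]:
                    cost[w] = c_terminal
        total = 0.0
        for e in effectors:
            if e in dist and e != gene:
                total += 1.0 / (dist[e] * max(cost[e], 1.0))
        per_network.append(total)
    if not per_network:
        return 0.0
    return float(np.mean(per_network))


def robustness_score(
    gene,
    networks: Sequence[CausalNetwork],
    kda_results: Sequence[pd.DataFrame],
) -> tuple:
    """(#datasets + #gene-set tags + #model types, total networks) in which
    ``gene`` is a key driver; the second element is the tie-breaker."""
    if len(networks) != len(kda_results):
        raise ValueError("kda_results must cover all networks")
    datasets, gene_sets, model_types, count = set(), set(), set(), 0
    for net, table in zip(networks, kda_results):
        if gene in table.index and bool(table.loc[gene, "is_key_driver"]):
            count += 1
            datasets.add(net.metadata.get("dataset", "?"))
            gene_sets.add(net.metadata.get("gene_set", "?"))
            model_types.add(net.metadata.get("model_type", "?"))
    score = len(datasets) + len(gene_sets) + len(model_types) if count else 0
    return score, count


def aggregate_key_drivers(
    networks: Sequence[CausalNetwork],
    kda_results: Sequence[pd.DataFrame],
    effectors: Sequence,
    fallback_to_all: bool = True,
) -> pd.DataFrame:
    """Per-gene aggregate table: impact and robustness scores with dense ranks.

    Covers every gene flagged as a key driver in at least one network. On
    small cohorts no gene may reach significance; with ``fallback_to_all``
    the table then covers every tested gene (the ``n_networks`` column
    records 0 driver calls) so the ranking ledger stays well defined.
    """
    drivers = set()
    for table in kda_results:
        drivers |= set(table.index[table["is_key_driver"]])
    if not drivers and fallback_to_all:
        for table in kda_results:
            drivers |= set(table.index)
    rows = []
    for gene in sorted(drivers, key=str):
        imp = impact_score(gene, networks, effectors)
        rob, count = robustness_score(gene, networks, kda_results)
        best_q = min(
            float(t.loc[gene, "q"]) for t in kda_results if gene in t.index
        )
        rows.append({"gene": gene, "impact_score": imp, "robustness_score": rob,
                     "n_networks": count, "best_q": best_q})
    if not rows:
        return pd.DataFrame(
            columns=["gene", "impact_score", "robustness_score", "n_networks",
                     "best_q", "impact_rank", "robustness_rank"]
        ).set_index("gene")
    table = pd.DataFrame(rows).set_index("gene")
    table["impact_rank"] = (
        table["impact_score"].rank(ascending=False, method="dense").astype(int)
    )
    # robustness ties broken by network count
    rob_key = table["robustness_score"] + table["n_networks"] / (len(networks) * 10 + 1)
    table["robustness_rank"] = rob_key.rank(ascending=False, method="dense").astype(int)
    return table.sort_values(["impact_rank", "robustness_rank"])


def rank_and_prioritize(
    records: pd.DataFrame,
    top_n: int = 50,
    replicated_rank_filter: int = 15,
    top_unique: int = 3,
    curated_sets: Mapping[str, Sequence] | None = None,
    extra_picks: Sequence | None = None,
) -> pd.DataFrame:
    """Rank-based selection ledger for key-driver prioritization.

    From the top-``top_n`` genes of the impact and robustness rankings:
    replicated genes (in both lists) are kept when ranked ≤
    ``replicated_rank_filter`` in at least one list; the best ``top_unique``
    non-replicated genes of each list are added; curated-set members found in
    either top list are added; user-flagged extra picks from the remaining
    top-list genes are added last. Each selected gene carries its selection
    rule.
    """
    for col in ("impact_rank", "robustness_rank"):
        if col not in records.columns:
            raise ValueError(f"records lack column {col!r}")
    if records.index.duplicated().any():
        raise ValueError("conflicting duplicate records")

    by_impact = records[records["impact_rank"] <= top_n]
    by_robust = records[records["robustness_rank"] <= top_n]
    top_either = set(by_impact.index) | set(by_robust.index)
    replicated = set(by_impact.index) & set(by_robust.index)

    selections: dict = {}

    def select(gene, label):
        if gene not in selections:
            selections[gene] = label

    for gene in sorted(replicated, key=str):
        r1 = records.loc[gene, "impact_rank"]
        r2 = records.loc[gene, "robustness_rank"]
        if min(r1, r2) <= replicated_rank_filter:
            select(gene, "replicated-top")

    for frame, rank_col, label in [
        (by_impact, "impact_rank", "unique-top-impact"),
        (by_robust, "robustness_rank", "unique-top-robustness"),
    ]:
        unique = frame.loc[~frame.index.isin(replicated)].sort_values(rank_col)
        for gene in unique.index[:top_unique]:
            select(gene, label)

    for name, members in (curated_sets or {}).items():
        for gene in sorted(set(members) & top_either, key=str):
            select(gene, f"curated:{name}")

    for gene in extra_picks or []:
        if gene in top_either:
            select(gene, "extra-pick")

    out = records.loc[sorted(selections, key=str)].copy()
    out["selection"] = [selections[g] for g in out.index]
    return out.sort_values(["impact_rank", "robustness_rank"])
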