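"""Seed-set expansion over a background pathway graph by depth-first search.

The background interaction graph may mix directed and undirected edges.
Undirected edges are replaced by two anti-parallel directed edges that are
mutually exclusive within a single path. A DFS is launched from every seed
gene; a path stops when it reaches K edges or has no unvisited successor.
A stopped path containing at least two seed genes contributes all nodes from
the start up to the seed farthest along the path; the expanded set is the
union of the seeds with all such intermediate genes. Only the resulting node
set feeds network learning — the pathway edges themselves are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

__all__ = ["MixedGraph", "directionalize", "expand_seed_genes", "read_pathway_graph"]


@dataclass
class MixedGraph:
    """A graph with both directed edges and undirected (unordered) edges."""

    nodes: set = field(default_factory=set)
    directed: set = field(default_factory=set)    # (u, v) ordered pairs
    undirected: set = field(default_factory=set)  # frozenset({u, v})

    def add_directed(self, u, v, source: str | None = None) -> None:
        if u == v:
            return
        self.nodes |= {u, v}
        self.directed.add((u, v))

    def add_undirected(self, u, v, source: str | None = None) -> None:
        if u == v:
            return
        self.nodes |= {u, v}
        self.undirected.add(frozenset((u, v)))

    def validate(self) -> None:
        for pair in self.undirected:
            u, v = tuple(pair)
            if (u, v) in self.directed or (v, u) in self.directed:
                raise ValueError(f"edge {u}-{v} appears both directed and undirected")


def directionalize(graph: MixedGraph):
    """Expand undirected edges into anti-parallel directed pairs.

    Returns ``(successors, pair_id)`` where ``successors`` maps each node to
    its sorted successor list and ``pair_id`` maps each directed edge arising
    from an undirected one to a shared identifier (the two anti-parallel
    edges of one undirected pair are mutually exclusive within a path).
    """
    successors: dict = {n: set() for n in graph.nodes}
    pair_id: dict = {}
    for u, v in graph.directed:
        successors.setdefault(u, set()).add(v)
        successors.setdefault(v, set())
    for pid, pair in enumerate(sorted(graph.undirected, key=lambda p: tuple(sorted(p, key=str)))):
        u, v = sorted(pair, key=str)
        successors.setdefault(u, set()).add(v)
        successors.setdefault(v, set()).add(u)
        pair_id[(u, v)] = pid
        pair_id[(v, u)] = pid
    ordered = {n: sorted(s, key=str) for n, s in successors.items()}
    return ordered, pair_id


def expand_seed_genes(graph: MixedGraph, seeds: Iterable, K: int = 4) -> set:
    """Expand a seed gene set with intermediates on bounded DFS paths.

    Paths are node-simple, at most ``K`` edges long, and never use both
    anti-parallel copies of one undirected edge. When a path stops (length K
    reached, or no unvisited successor) and contains ≥ 2 seeds, the nodes
    from the start up to the seed at maximum along-path distance are added.
    Seeds absent from the graph are ignored in traversal but kept in the
    output. Neighbor order is lexicographic, so the result is deterministic.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    seeds = set(seeds)
    succ, pair_id = directionalize(graph)
    missing = seeds - set(succ)
    if missing:
        logger.info("%d seed genes absent from the background graph", len(missing))

    result = set(seeds)

    def harvest(path: list) -> None:
        # farthest seed along the path = last seed occurrence
        last = -1
        n_seeds = 0
        for i, node in enumerate(path):
            if node in seeds:
                n_seeds += 1
                last = i
        if n_seeds >= 2:
            result.update(path[: last + 1])

    def dfs(path: list, on_path: set, used_pairs: set) -> None:
        node = path[-1]
        if len(path) - 1 >= K:
            harvest(path)
            return
        extended = False
        for child in succ.get(node, ()):
            if child in on_path:
                continue
            pid = pair_id.get((node, child))
            if pid is not None and pid in used_pairs:
                continue
            extended = True
            path.append(child)
            on_path.add(child)
            if pid is not None:
                used_pairs.add(pid)
            dfs(path, on_path, used_pairs)
            if pid is not None:
                used_pairs.discard(pid)
            on_path.discard(child)
            path.pop()
        if not extended:
            harvest(path)

    for s in sorted(seeds & set(succ), key=str):
        dfs([s], {s}, set())
    return result


def read_pathway_graph(
    path, directed_relations: Sequence[str] = ("directed",)
) -> MixedGraph:
    """Parse a background graph from SIF or 3-column TSV.

    Each line is ``source relation target`` (whitespace-separated SIF or
    tab-separated). Relations named in ``directed_relations`` yield directed
    edges; all others undirected. Duplicate edges collapse; self-loops are
    dropped and counted.
    """
    graph = MixedGraph()
    directed_relations = set(directed_relations)
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            src, rel, tgt = (p.strip() for p in parts)
            if not src or not tgt or not rel:
                raise ValueError(f"{path}:{lineno}: empty field")
            if src == tgt:
                n_self += 1
                continue
            if rel in directed_relations:
                graph.add_directed(src, tgt)
            else:
                graph.add_undirected(src, tgt)
    if n_self:
        logger.info("dropped %d self-loop lines from %s", n_self, path)
    # an unordered pair may not be both directed and undirected: directed wins
    for u, v in list(graph.directed):
        graph.undirected.discard(frozenset((u, v)))
    return graph
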