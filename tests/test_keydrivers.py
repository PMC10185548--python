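import itertools
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from neurokd.containers import CausalNetwork
from neurokd.keydrivers import (
    KdaConfig,
    aggregate_key_drivers,
    background_subnetwork,
    impact_score,
    kda,
    rank_and_prioritize,
    robustness_score,
)
from neurokd.stats import bh_fdr


def kda_oracle(network: CausalNetwork, targets, config: KdaConfig) -> pd.DataFrame:
    """Brute-force re-derivation: explicit path enumeration + exact
    hypergeometric tail by combinatorial summation."""
    g = network.graph
    targets = set(targets)
    # undirected neighborhoods by explicit BFS
    present = [t for t in targets if t in g]
    bg = set(present)
    for t in present:
        frontier, seen = {t}, {t}
        for _ in range(config.neighborhood_step):
            nxt = set()
            for u in frontier:
                nxt |= set(g.successors(u)) | set(g.predecessors(u))
            nxt -= seen
            seen |= nxt
            frontier = nxt
        bg |= seen
    sub = g.subgraph(bg)
    M = len(bg)
    rows = []
    for v in sorted(bg, key=str):
        n_t = len(targets & bg) - (1 if v in targets else 0)
        best_p, best_k = 1.0, 0
        for k in range(1, config.K + 1):
            # reachable within k directed steps via explicit enumeration
            reach = set()
            frontier = {v}
            for _ in range(k):
                frontier = {w for u in frontier for w in sub.successors(u)}
                reach |= frontier
            reach -= {v}
            if not reach:
                continue
            x = len(reach & targets)
            N, n_draw = M - 1, len(reach)
            tail = sum(
                comb(n_t, i) * comb(N - n_t, n_draw - i)
                for i in range(x, min(n_t, n_draw) + 1)
            ) / comb(N, n_draw)
            if tail < best_p or best_k == 0:
                best_p, best_k = tail, k
        rows.append({"gene": v, "p": best_p})
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table


def random_network(rng, n_nodes=12, p_edge=0.2) -> CausalNetwork:
    g = nx.DiGraph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    g.add_nodes_from(nodes)
    for u, v in itertools.permutations(nodes, 2):
        if rng.random() < p_edge:
            g.add_edge(u, v, posterior=1.0)
    return CausalNetwork(g)


class TestBackgroundSubnetwork:
    def test_k_zero_is_targets_in_network(self):
        net = CausalNetwork(nx.DiGraph([("a", "b"), ("b", "c")]))
        assert background_subnetwork(net, ["a", "zzz"], 0) == {"a"}

    def test_chain_k2(self):
        net = CausalNetwork(nx.DiGraph([("a", "b"), ("b", "c")]))
        assert background_subnetwork(net, ["a"], 2) == {"a", "b", "c"}

    def test_large_k_covers_component(self):
        g = nx.DiGraph([("a", "b"), ("b", "c"), ("x", "y")])
        net = CausalNetwork(g)
        assert background_subnetwork(net, ["a"], 10) == {"a", "b", "c"}

    def test_missing_targets_error(self):
        net = CausalNetwork(nx.DiGraph([("a", "b")]))
        with pytest.raises(ValueError):
            background_subnetwork(net, ["zzz"], 2)


class TestKda:
    def test_hub_flagged_with_exact_oracle_p(self):
        g = nx.DiGraph()
        for i in range(10):
            g.add_edge("h", f"l{i}", posterior=1.0)
        g.add_edge("l0", "z", posterior=1.0)
        for i in range(40):
            g.add_edge("z", f"p{i}", posterior=1.0)
        net = CausalNetwork(g)
        targets = [f"l{i}" for i in range(8)]
        cfg = KdaConfig(K=6)
        table = kda(net, targets, cfg)
        oracle = kda_oracle(net, targets, cfg)
        assert bool(table.loc["h", "is_key_driver"])
        assert table.loc["h", "p"] == pytest.approx(oracle.loc["h", "p"], rel=1e-12)

    def test_sink_never_key_driver(self):
        g = nx.DiGraph([("a", "b"), ("a", "c"), ("a", "d")])
        net = CausalNetwork(g)
        table = kda(net, ["b", "c", "d"], KdaConfig(K=3))
        for sink in ("b", "c", "d"):
            assert not bool(table.loc[sink, "is_key_driver"])

    def test_matches_oracle_on_random_networks(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            net = random_network(rng, n_nodes=rng.integers(6, 15))
            nodes = list(net.graph.nodes)
            targets = list(rng.choice(nodes, size=4, replace=False))
            cfg = KdaConfig(K=int(rng.integers(1, 6)))
            try:
                table = kda(net, targets, cfg)
            except ValueError:
                continue
            oracle = kda_oracle(net, targets, cfg)
            merged = table.join(oracle, rsuffix="_oracle")
            assert np.allclose(merged["p"], merged["p_oracle"], rtol=1e-10), trial
            assert np.allclose(merged["q"], merged["q_oracle"], rtol=1e-10), trial

    def test_downstream_sets_nested_and_p_monotone_in_K(self):
        from neurokd.keydrivers import downstream_sets

        rng = np.random.default_rng(1)
        net = random_network(rng, n_nodes=12, p_edge=0.25)
        nodes = list(net.graph.nodes)
        targets = nodes[:4]
        v = nodes[5]
        sets = downstream_sets(net.graph, v, 6)
        for a, b in zip(sets, sets[1:]):
            assert a <= b
        p_prev = 1.0
        for K in (1, 2, 3, 4):
            table = kda(net, targets, KdaConfig(K=K))
            if v in table.index:
                assert table.loc[v, "p"] <= p_prev + 1e-12
                p_prev = table.loc[v, "p"]

    def test_empty_targets_rejected(self):
        net = CausalNetwork(nx.DiGraph([("a", "b")]))
        with pytest.raises(ValueError):
            kda(net, [], KdaConfig())


class TestImpactScore:
    def test_direct_sole_parent_contribution_one(self):
        net = CausalNetwork(nx.DiGraph([("g", "e")]))
        assert impact_score("g", [net], ["e"]) == pytest.approx(1.0)

    def test_intermediate_with_indegree_two(self):
        g = nx.DiGraph([("g", "x"), ("u", "x"), ("x", "e")])
        net = CausalNetwork(g)
        assert impact_score("g", [net], ["e"]) == pytest.approx(1.0 / (2 * 2))

    def test_extra_hop_never_increases_contribution(self):
        direct = CausalNetwork(nx.DiGraph([("g", "e")]))
        hop = CausalNetwork(nx.DiGraph([("g", "x"), ("x", "e")]))
        assert impact_score("g", [hop], ["e"]) <= impact_score("g", [direct], ["e"])

    def test_disconnected_nodes_do_not_shift_score(self):
        g1 = nx.DiGraph([("g", "e")])
        g2 = g1.copy()
        g2.add_nodes_from(["iso1", "iso2"])
        assert impact_score("g", [CausalNetwork(g1)], ["e"]) == pytest.approx(
            impact_score("g", [CausalNetwork(g2)], ["e"])
        )

    def test_absent_gene_scores_zero(self):
        net = CausalNetwork(nx.DiGraph([("a", "b")]))
        assert impact_score("zzz", [net], ["b"]) == 0.0

    def test_min_coregulator_path_chosen(self):
        # two length-2 routes to e; one through a hub with in-degree 3
        g = nx.DiGraph([("g", "x"), ("g", "h"), ("x", "e"), ("h", "e"),
                        ("u1", "h"), ("u2", "h")])
        net = CausalNetwork(g)
        # best path g->x->e: L=2, C=indeg(x)=1 -> 0.5
        assert impact_score("g", [net], ["e"]) == pytest.approx(0.5)


class TestRobustnessScore:
    def _networks(self, metas):
        nets = []
        for m in metas:
            nets.append(CausalNetwork(nx.DiGraph([("a", "b")]), dict(m)))
        return nets

    def _kda_tables(self, flags):
        out = []
        for f in flags:
            out.append(pd.DataFrame({"q": [0.01], "is_key_driver": [f]},
                                    index=pd.Index(["a"], name="gene")))
        return out

    def test_full_replication_maximum(self):
        metas = [
            {"dataset": d, "gene_set": s, "model_type": t}
            for d in ("MAYO", "ROSMAP") for s in ("seed", "expanded")
            for t in ("bayes", "predictive")
        ][:11] + []
        nets = self._networks(metas * 1)
        tables = self._kda_tables([True] * len(nets))
        score, count = robustness_score("a", nets, tables)
        assert score == 6
        assert count == len(nets)

    def test_single_network_score_three(self):
        nets = self._networks([{"dataset": "MAYO", "gene_set": "seed",
                                "model_type": "bayes"}])
        score, count = robustness_score("a", nets, self._kda_tables([True]))
        assert (score, count) == (3, 1)

    def test_never_driver_scores_zero(self):
        nets = self._networks([{"dataset": "MAYO", "gene_set": "seed",
                                "model_type": "bayes"}])
        score, count = robustness_score("a", nets, self._kda_tables([False]))
        assert (score, count) == (0, 0)


class TestPrioritization:
    def _records(self):
        genes = [f"g{i}" for i in range(100)]
        rng = np.random.default_rng(2)
        impact = np.arange(1, 101)
        robustness = np.arange(1, 101)
        rng.shuffle(robustness)
        return pd.DataFrame(
            {"impact_rank": impact, "robustness_rank": robustness},
            index=pd.Index(genes, name="gene"),
        )

    def test_rank_one_both_lists_replicated_top(self):
        records = self._records()
        records.loc["g0", ["impact_rank", "robustness_rank"]] = [1, 1]
        out = rank_and_prioritize(records)
        assert out.loc["g0", "selection"] == "replicated-top"

    def test_deep_replicated_filtered_out(self):
        records = self._records()
        records.loc["deep"] = [40, 44]
        out = rank_and_prioritize(records)
        assert "deep" not in out.index or out.loc["deep", "selection"] != "replicated-top"

    def test_curated_member_labelled(self):
        records = self._records()
        # a gene in the impact top-50 only, rank 30
        gene = records.index[(records["impact_rank"] == 30)][0]
        if records.loc[gene, "robustness_rank"] <= 50:
            records.loc[gene, "robustness_rank"] = 90
        out = rank_and_prioritize(records, curated_sets={"agora": [gene]})
        assert gene in out.index
        assert out.loc[gene, "selection"].startswith(("curated", "unique"))

    def test_duplicate_records_rejected(self):
        records = self._records()
        dup = pd.concat([records, records.iloc[[0]]])
        with pytest.raises(ValueError):
            rank_and_prioritize(dup)


class TestAggregate:
    def test_planted_regulator_recovery(self):
        """A root feeding most DE genes ranks among the top drivers."""
        from neurokd.synthetic import CohortConfig, simulate_bulk_cohort

        top3 = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cfg = CohortConfig(n_subjects=200, n_cases=100, n_genes=60,
                               n_variants=30, seed=seed)
            bulk, geno, cov, truth = simulate_bulk_cohort(cfg)
            reg = truth.key_regulators[0]
            net = CausalNetwork(truth.dag.copy(), {"dataset": "truth"})
            table = kda(net, truth.de_genes["neuron"], KdaConfig(K=6))
            ranked = table.sort_values(["q", "p"]).index.tolist()
            top3 += reg in ranked[:3]
        assert top3 / n_seeds >= 0.9
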