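"""Random-walk rankings, flow clustering, and k-step propagation."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ballastflow.dispersal import (
    WalkConfig,
    cluster_network,
    greedy_map_equation,
    map_equation,
    propagate_steps,
    random_walk_with_resets,
    rank_direct_vs_indirect,
    transition_matrix,
)
from ballastflow.flow_networks import HONConfig, build_fon, build_sf_hon, \
    extract_hon_rules


def digraph(edges, weighting=None):
    g = nx.DiGraph()
    if weighting:
        g.graph["weighting"] = weighting
    nodes = {n for e in edges for n in e[:2]}
    for n in nodes:
        g.add_node(n, physical_port=n, context=())
    for u, v, w in edges:
        g.add_edge(u, v, weight=w)
    return g


def dense_stationary(net, cfg=WalkConfig()):
    """Independent oracle: dense linear solve of the stationary equations."""
    nodes, P, dangling = transition_matrix(net)
    n = len(nodes)
    r = np.ones(n) / n
    A = cfg.damping * (P + np.outer(dangling.astype(float), r)) \
        + (1 - cfg.damping) * np.outer(np.ones(n), r)
    B = np.vstack([A.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    x, *_ = np.linalg.lstsq(B, b, rcond=None)
    return dict(zip(nodes, x))


class TestTransitionMatrix:
    def test_fon_fixture_row(self, worked_trajectories):
        fon = build_fon(worked_trajectories)
        nodes, P, _ = transition_matrix(fon)
        i = {n: k for k, n in enumerate(nodes)}
        assert P[i["Murmansk"], i["Bodo"]] == pytest.approx(0.5)
        assert P[i["Murmansk"], i["Nuuk"]] == pytest.approx(0.5)

    def test_hon_fixture_row(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, HONConfig(
            max_order=2, min_support=1, divergence_threshold=0.0))
        hon = build_sf_hon(rules)
        nodes, P, _ = transition_matrix(hon)
        i = {n: k for k, n in enumerate(nodes)}
        mt = ("Murmansk", ("Tromso",))
        assert P[i[mt], i[("Bodo", ())]] == pytest.approx(2 / 3)
        assert P[i[mt], i[("Nuuk", ())]] == pytest.approx(1 / 3)

    def test_dangling_row_marked(self):
        g = digraph([("A", "B", 1.0)])
        nodes, _P, dangling = transition_matrix(g)
        assert dict(zip(nodes, dangling)) == {"A": False, "B": True}


class TestRandomWalk:
    def test_two_node_symmetry(self):
        g = digraph([("A", "B", 1.0), ("B", "A", 1.0)])
        walk = random_walk_with_resets(g)
        assert walk.scores["A"] == pytest.approx(0.5, abs=1e-9)
        assert walk.scores["B"] == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("seed,n", [(0, 5), (1, 12), (2, 20)])
    def test_matches_dense_solver_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        g = nx.DiGraph()
        for i in range(n):
            g.add_node(f"P{i}", physical_port=f"P{i}", context=())
        for i in range(n):
            for j in rng.choice(n, size=3, replace=False):
                if i != j:
                    g.add_edge(f"P{i}", f"P{j}", weight=float(rng.uniform(0.1, 1)))
        walk = random_walk_with_resets(g)
        oracle = dense_stationary(g)
        assert sum(walk.scores.values()) == pytest.approx(1.0, abs=1e-9)
        for node, score in oracle.items():
            assert walk.node_scores[node] == pytest.approx(score, abs=1e-8)

    def test_relabeling_invariance(self):
        edges = [("A", "B", 1.0), ("B", "C", 2.0), ("C", "A", 1.0)]
        g1 = digraph(edges)
        g2 = digraph([(u + "x", v + "x", w) for u, v, w in edges])
        w1 = random_walk_with_resets(g1).scores
        w2 = random_walk_with_resets(g2).scores
        for k, v in w1.items():
            assert w2[k + "x"] == pytest.approx(v, abs=1e-10)

    def test_nonconvergence_reports_residual(self):
        g = digraph([("A", "B", 1.0), ("A", "C", 1.0), ("B", "A", 1.0)])
        with pytest.raises(RuntimeError, match="residual"):
            random_walk_with_resets(g, WalkConfig(tolerance=1e-16, max_iter=3))

    def test_hon_scores_summed_per_physical_port(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, HONConfig(
            max_order=2, min_support=1, divergence_threshold=0.0))
        hon = build_sf_hon(rules)
        walk = random_walk_with_resets(hon)
        assert sum(walk.scores.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(walk.scores) == {"Tromso", "Narvik", "Murmansk", "Bodo", "Nuuk"}


class TestRankComparison:
    def test_order1_hon_ranking_equals_fon_ranking(self, worked_trajectories):
        fon = build_fon(worked_trajectories)
        hon = build_sf_hon(extract_hon_rules(worked_trajectories,
                                             HONConfig(max_order=1)))
        table = rank_direct_vs_indirect(fon, hon)
        fon_walk = random_walk_with_resets(fon)
        for row in table.itertuples():
            assert row.indirect_rank == fon_walk.ranks[row.port]

    def test_single_port_network(self):
        g = digraph([])
        g.add_node("A", physical_port="A", context=())
        table = rank_direct_vs_indirect(g, g)
        assert table.iloc[0].direct_rank == 1 and table.iloc[0].indirect_rank == 1

    def test_port_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rank_direct_vs_indirect(digraph([("A", "B", 1.0)]),
                                    digraph([("A", "C", 1.0)]))

    def test_gateway_hub_gains_rank_indirectly(self):
        # hub H has weak direct in-edges but concentrates the cluster's flow
        edges = [(f"F{i}", t, 0.9) for i, t in zip(range(6), ["A", "B", "C"] * 2)]
        edges += [(x, "H", 0.01) for x in "ABC"]
        edges += [("H", f"F{i}", 0.05) for i in range(6)]
        g = digraph(edges, weighting="risk")
        table = rank_direct_vs_indirect(g, g).set_index("port")
        assert table.loc["H"].indirect_rank < table.loc["H"].direct_rank


class TestClustering:
    def two_cliques(self):
        g = nx.DiGraph()
        edges = []
        for block, nodes in enumerate((list("abcde"), list("vwxyz"))):
            for u, v in itertools.permutations(nodes, 2):
                edges.append((u, v, 1.0))
        edges += [("e", "v", 0.01), ("v", "e", 0.01)]
        return digraph(edges)

    def test_two_cliques_split_matches_exhaustive_oracle(self):
        g = self.two_cliques()
        part = cluster_network(g, seed=0)
        groups = {}
        for n, c in part.items():
            groups.setdefault(c, set()).add(n)
        assert sorted(map(sorted, groups.values())) == [list("abcde"),
                                                        list("vwxyz")]
        # oracle: exhaustive search over all 2-partitions of the 10 nodes
        nodes = sorted(g.nodes)
        best, best_val = None, np.inf
        for mask in range(1, 2 ** 9):  # fix node 0's side to halve the space
            part2 = {nodes[0]: 0}
            for k, n in enumerate(nodes[1:]):
                part2[n] = (mask >> k) & 1
            val = map_equation(g, part2)
            if val < best_val:
                best, best_val = part2, val
        oracle_groups = {}
        for n, c in best.items():
            oracle_groups.setdefault(c, set()).add(n)
        assert sorted(map(sorted, oracle_groups.values())) == \
            sorted(map(sorted, groups.values()))

    def test_infomap_backend_agrees_on_planted_partition(self):
        g = self.two_cliques()
        part = cluster_network(g, seed=0, backend="infomap")
        groups = {}
        for n, c in part.items():
            groups.setdefault(c, set()).add(n)
        assert sorted(map(sorted, groups.values())) == [list("abcde"),
                                                        list("vwxyz")]

    def test_complete_uniform_graph_one_cluster(self):
        edges = [(u, v, 1.0) for u, v in itertools.permutations("abcd", 2)]
        part = cluster_network(digraph(edges), seed=0)
        assert len(set(part.values())) == 1

    def test_disconnected_components_never_merged(self):
        edges = [("a", "b", 1.0), ("b", "a", 1.0), ("x", "y", 1.0),
                 ("y", "x", 1.0)]
        part = cluster_network(digraph(edges), seed=0)
        assert part["a"] == part["b"]
        assert part["x"] == part["y"]
        assert part["a"] != part["x"]

    def test_deterministic_given_seed(self):
        g = self.two_cliques()
        assert cluster_network(g, seed=3) == cluster_network(g, seed=3)


class TestPropagation:
    def test_hon_fixture_one_step(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, HONConfig(
            max_order=2, min_support=1, divergence_threshold=0.0))
        hon = build_sf_hon(rules)
        trace = propagate_steps(hon, ("Murmansk", ("Tromso",)), 1)
        assert trace.steps[0] == pytest.approx({"Bodo": 2 / 3, "Nuuk": 1 / 3})

    def test_fon_fixture_one_step(self, worked_trajectories):
        fon = build_fon(worked_trajectories)
        trace = propagate_steps(fon, "Murmansk", 1)
        assert trace.steps[0] == pytest.approx({"Bodo": 0.5, "Nuuk": 0.5})

    def test_absorbing_end_empties_step_two(self):
        g = digraph([("A", "B", 1.0)])
        trace = propagate_steps(g, "A", 2)
        assert trace.steps[0] == {"B": 1.0}
        assert trace.steps[1] == {}
        assert trace.lost == [0.0, 1.0]

    def test_mass_conserved_up_to_reported_loss(self, worked_trajectories):
        fon = build_fon(worked_trajectories)
        trace = propagate_steps(fon, "Tromso", 3)
        for s in range(3):
            mass = sum(trace.steps[s].values()) + sum(trace.lost[:s + 1])
            assert mass == pytest.approx(1.0, abs=1e-12)

    def test_reachable_support_nested_in_out_neighborhood(self, worked_trajectories):
        fon = build_fon(worked_trajectories)
        trace = propagate_steps(fon, "Tromso", 2)
        support1 = set(trace.steps[0])
        reachable = {v for u in support1 for v in fon.successors(u)}
        assert set(trace.steps[1]) <= reachable

    def test_high_risk_edges_flagged(self, worked_trajectories):
        fon = build_fon(worked_trajectories)
        trace = propagate_steps(fon, "Murmansk", 1, report_threshold=0.4)
        assert {(u, v) for u, v, _w in trace.highlighted[0]} == \
            {("Murmansk", "Bodo"), ("Murmansk", "Nuuk")}

    def test_unknown_start_rejected(self):
        with pytest.raises(KeyError):
            propagate_steps(digraph([("A", "B", 1.0)]), "Z", 1)
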