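"""Dispersal dynamics on species-flow networks: random-walk port rankings,
flow-based clustering, and k-step propagation traces.

A port's risk of receiving *indirect* dispersal is modelled as the
probability that a random walker on the species-flow network visits it. The
walker follows outgoing edges with probability proportional to their weight
(the normalized relative risk) and, with probability 1 - damping, resets to
a uniformly chosen port — so it never gets trapped in loops and can follow
unobserved routes. On a higher-order network the reset mass enters at
first-order (context-free) nodes, and node probabilities are summed per
physical port before ranking.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, field
from typing import Callable, Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .risk import aggregate_pathway_risk

__all__ = [
    "WalkConfig",
    "PortRanking",
    "PropagationTrace",
    "transition_matrix",
    "random_walk_with_resets",
    "rank_direct_vs_indirect",
    "map_equation",
    "greedy_map_equation",
    "cluster_network",
    "propagate_steps",
]


@dataclass(frozen=True)
class WalkConfig:
    """Random-walk parameters: edge-following probability (damping),
    convergence tolerance on the L1 change of successive iterates, and an
    iteration cap."""

    damping: float = 0.85
    tolerance: float = 1e-10
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.damping < 1.0:
            raise ValueError("damping must lie in (0, 1)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PortRanking:
    """Visit probabilities summed per physical port, with deterministic
    ranks (1 = highest; ties broken lexicographically by port id)."""

    scores: dict[str, float]
    ranks: dict[str, int]
    node_scores: dict[Hashable, float] = field(default_factory=dict)
    n_iter: int = 0
    residual: float = 0.0


def _node_order(net: nx.DiGraph) -> list[Hashable]:
    return sorted(net.nodes, key=str)


def transition_matrix(
    net: nx.DiGraph,
) -> tuple[list[Hashable], np.ndarray, np.ndarray]:
    """Row-stochastic transition operator of a weighted network.

    Returns (nodes, P, dangling) where rows of ``P`` with outgoing edges are
    weight-normalized to sum to 1 and ``dangling`` flags rows without
    out-edges (their mass is handed to the reset distribution by the walk).
    """
    if net.number_of_nodes() == 0:
        raise ValueError("network has no nodes")
    nodes = _node_order(net)
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    P = np.zeros((n, n))
    for u, v, d in net.edges(data=True):
        P[index[u], index[v]] = d["weight"]
    rowsum = P.sum(axis=1)
    dangling = rowsum == 0
    P[~dangling] /= rowsum[~dangling, None]
    return nodes, P, dangling


def _reset_vector(net: nx.DiGraph, nodes: Sequence[Hashable]) -> np.ndarray:
    """Uniform over physical ports, entering at first-order nodes."""
    first_order = np.array(
        [not net.nodes[n].get("context", ()) for n in nodes], dtype=bool)
    if not first_order.any():
        first_order[:] = True
    r = first_order.astype(float)
    return r / r.sum()


def random_walk_with_resets(
    net: nx.DiGraph, cfg: WalkConfig = WalkConfig()
) -> PortRanking:
    """Stationary visit probabilities of the damped random walk.

    Power iteration on x' = d·(xP + m·r) + (1-d)·r where m is the mass
    sitting on dangling nodes and r the uniform first-order reset vector;
    converged when the L1 change drops below the tolerance. Raises on
    non-convergence, reporting the residual.
    """
    nodes, P, dangling = transition_matrix(net)
    r = _reset_vector(net, nodes)
    x = r.copy()
    for it in range(1, cfg.max_iter + 1):
        x_new = cfg.damping * (x @ P + x[dangling].sum() * r) + (1 - cfg.damping) * r
        residual = float(np.abs(x_new - x).sum())
        x = x_new
        if residual < cfg.tolerance:
            break
    else:
        raise RuntimeError(
            f"random walk did not converge in {cfg.max_iter} iterations "
            f"(residual {residual:.3e})")
    node_scores = {n: float(s) for n, s in zip(nodes, x)}
    scores: dict[str, float] = {}
    for n, s in node_scores.items():
        port = net.nodes[n].get("physical_port", str(n))
        scores[port] = scores.get(port, 0.0) + s
    ranks = _rank(scores)
    return PortRanking(scores=scores, ranks=ranks, node_scores=node_scores,
                       n_iter=it, residual=residual)


def _rank(scores: Mapping[str, float]) -> dict[str, int]:
    ordered = sorted(scores, key=lambda p: (-scores[p], p))
    return {p: i + 1 for i, p in enumerate(ordered)}


def rank_direct_vs_indirect(
    fon: nx.DiGraph, hon: nx.DiGraph, cfg: WalkConfig = WalkConfig()
) -> pd.DataFrame:
    """Side-by-side port ranking: direct (aggregated incoming pathway risk on
    the first-order network) vs indirect (random-walk visit probability on
    the higher-order network).

    ``rank_shift`` = direct rank - indirect rank (> 0: the port matters more
    for indirect dispersal than its direct connections suggest).
    """
    fon_ports = {fon.nodes[n].get("physical_port", str(n)) for n in fon.nodes}
    hon_ports = {hon.nodes[n]["physical_port"] for n in hon.nodes}
    if fon_ports != hon_ports:
        raise ValueError(
            "first- and higher-order networks cover different ports: "
            f"{sorted(fon_ports ^ hon_ports)}")
    risk_mode = fon.graph.get("weighting") == "risk"
    direct: dict[str, float] = {p: 0.0 for p in fon_ports}
    for j in fon.nodes:
        ws = [d["weight"] for _u, _v, d in fon.in_edges(j, data=True)]
        port = fon.nodes[j].get("physical_port", str(j))
        direct[port] = aggregate_pathway_risk(ws) if risk_mode else float(sum(ws))
    direct_rank = _rank(direct)
    walk = random_walk_with_resets(hon, cfg)
    rows = [
        {
            "port": p,
            "direct_risk": direct[p],
            "direct_rank": direct_rank[p],
            "indirect_score": walk.scores.get(p, 0.0),
            "indirect_rank": walk.ranks[p],
            "rank_shift": direct_rank[p] - walk.ranks[p],
        }
        for p in sorted(fon_ports)
    ]
    return pd.DataFrame(rows).sort_values("indirect_rank").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Flow-based clustering (map-equation family)
# ---------------------------------------------------------------------------

def _entropy_terms(ps: Sequence[float]) -> float:
    total = sum(ps)
    if total <= 0:
        return 0.0
    return -sum(p / total * math.log2(p / total) for p in ps if p > 0) * total


def _walk_rates(net: nx.DiGraph, cfg: WalkConfig) -> tuple[
        list[Hashable], np.ndarray, np.ndarray, dict[Hashable, int]]:
    nodes, P, _dangling = transition_matrix(net)
    walk = random_walk_with_resets(net, cfg)
    p = np.array([walk.node_scores[n] for n in nodes])
    return nodes, P, p, {n: i for i, n in enumerate(nodes)}


def _map_equation_core(net: nx.DiGraph, partition: Mapping[Hashable, int],
                       P: np.ndarray, p: np.ndarray,
                       index: Mapping[Hashable, int]) -> float:
    modules: dict[int, list[Hashable]] = {}
    for node, m in partition.items():
        modules.setdefault(m, []).append(node)
    q: dict[int, float] = {}
    for m, members in modules.items():
        exit_flow = 0.0
        for u in members:
            i = index[u]
            for v in net.successors(u):
                if partition[v] != m:
                    exit_flow += p[i] * P[i, index[v]]
        q[m] = exit_flow
    L = _entropy_terms(list(q.values()))
    for m, members in modules.items():
        L += _entropy_terms([q[m]] + [p[index[u]] for u in members])
    return float(L)


def map_equation(net: nx.DiGraph, partition: Mapping[Hashable, int],
                 cfg: WalkConfig = WalkConfig()) -> float:
    """Two-level map-equation description length (bits) of a partition.

    Node visit rates come from the damped random walk; module exit flows
    ignore teleportation. Lower is better: a good partition compresses the
    walk by spending few bits switching modules.
    """
    _nodes, P, p, index = _walk_rates(net, cfg)
    return _map_equation_core(net, partition, P, p, index)


def greedy_map_equation(net: nx.DiGraph, seed: int = 0,
                        cfg: WalkConfig = WalkConfig()) -> dict[Hashable, int]:
    """Greedy agglomerative search minimizing the two-level map equation.

    Starts from singletons and repeatedly moves single nodes to a
    neighboring module when that lowers the description length, sweeping in
    a seed-shuffled order until a full sweep makes no improvement.
    """
    rng = _random.Random(seed)
    nodes = _node_order(net)
    if not nodes:
        return {}
    partition = {n: i for i, n in enumerate(nodes)}
    _n, P, p, index = _walk_rates(net, cfg)
    best = _map_equation_core(net, partition, P, p, index)
    improved = True
    while improved:
        improved = False
        order = nodes[:]
        rng.shuffle(order)
        for u in order:
            neigh_modules = {partition[v] for v in
                             set(net.successors(u)) | set(net.predecessors(u))}
            for m in sorted(neigh_modules - {partition[u]}):
                trial = dict(partition)
                trial[u] = m
                val = _map_equation_core(net, trial, P, p, index)
                if val < best - 1e-12:
                    partition, best = trial, val
                    improved = True
                    break
    return _canonical_partition(nodes, partition)


def _infomap_backend(net: nx.DiGraph, seed: int) -> dict[Hashable, int]:
    import igraph

    nodes = _node_order(net)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in net.edges]
    weights = [float(net.edges[u, v]["weight"]) for u, v in net.edges]
    g = igraph.Graph(n=len(nodes), edges=edges, directed=True)
    state = _random.getstate()
    try:
        _random.seed(seed)
        clustering = g.community_infomap(edge_weights=weights or None, trials=10)
    finally:
        _random.setstate(state)
    partition = {n: clustering.membership[index[n]] for n in nodes}
    return _canonical_partition(nodes, partition)


def _canonical_partition(nodes: Sequence[Hashable],
                         partition: Mapping[Hashable, int]) -> dict[Hashable, int]:
    relabel: dict[int, int] = {}
    out: dict[Hashable, int] = {}
    for n in nodes:
        m = partition[n]
        if m not in relabel:
            relabel[m] = len(relabel)
        out[n] = relabel[m]
    return out


def cluster_network(
    net: nx.DiGraph,
    seed: int = 0,
    backend: str | Callable[[nx.DiGraph, int], dict[Hashable, int]] = "greedy",
) -> dict[Hashable, int]:
    """Flow-based partition of a species-flow network.

    The default backend is the in-package greedy map-equation search;
    ``backend="infomap"`` delegates to igraph's Infomap implementation of the
    same objective. Isolated nodes always get singleton clusters; the result
    is deterministic given the seed. Denser/stronger within-cluster
    connectivity is the objective's direction, not a guarantee.
    """
    if callable(backend):
        return backend(net, seed)
    if backend == "greedy":
        return greedy_map_equation(net, seed)
    if backend == "infomap":
        return _infomap_backend(net, seed)
    raise ValueError(f"unknown clustering backend {backend!r}")


# ---------------------------------------------------------------------------
# k-step propagation
# ---------------------------------------------------------------------------

@dataclass
class PropagationTrace:
    """Per-step reach of a dispersal front started at one node.

    ``steps[s]`` maps physical port → probability mass reaching it at step
    s+1; ``flows[s]`` lists (source label, target label, flow) edges;
    ``highlighted[s]`` is the subset of flows at or above the report
    threshold; ``lost[s]`` is the mass absorbed at dangling nodes (reported,
    never silently dropped).
    """

    start: Hashable
    steps: list[dict[str, float]]
    flows: list[list[tuple[str, str, float]]]
    highlighted: list[list[tuple[str, str, float]]]
    lost: list[float]


def propagate_steps(
    net: nx.DiGraph,
    start: Hashable,
    k: int,
    report_threshold: float = 0.0,
) -> PropagationTrace:
    """Push unit mass from ``start`` through k steps of the transition
    operator, reporting per-port reach and high-risk edges at every step.

    ``start`` may be a physical port (resolved to its first-order node on a
    higher-order network) or an explicit (port, context) node.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if start in net:
        node = start
    elif (start, ()) in net:
        node = (start, ())
    else:
        raise KeyError(f"start node {start!r} not in network")
    nodes, P, dangling = transition_matrix(net)
    index = {n: i for i, n in enumerate(nodes)}
    labels = [_label(net, n) for n in nodes]
    ports = [net.nodes[n].get("physical_port", str(n)) for n in nodes]
    x = np.zeros(len(nodes))
    x[index[node]] = 1.0
    steps: list[dict[str, float]] = []
    flows: list[list[tuple[str, str, float]]] = []
    highlighted: list[list[tuple[str, str, float]]] = []
    lost: list[float] = []
    for _ in range(k):
        lost.append(float(x[dangling].sum()))
        flow = x[:, None] * P
        x = x @ P
        step_flows = [
            (labels[i], labels[j], float(flow[i, j]))
            for i, j in zip(*np.nonzero(flow))
        ]
        flows.append(step_flows)
        highlighted.append([f for f in step_flows if f[2] >= report_threshold])
        reach: dict[str, float] = {}
        for j, port in enumerate(ports):
            if x[j] > 0:
                reach[port] = reach.get(port, 0.0) + float(x[j])
        steps.append(reach)
    return PropagationTrace(start=node, steps=steps, flows=flows,
                            highlighted=highlighted, lost=lost)


def _label(net: nx.DiGraph, node: Hashable) -> str:
    if isinstance(node, tuple):
        port, ctx = node
        return f"{port}|{'.'.join(ctx)}" if ctx else str(port)
    return str(node)
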