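"""First-order and higher-order species-flow networks from ship trajectories.

A first-order network (FON) aggregates direct port-to-port transitions and is
memoryless: the edge Murmansk→Bodo pools every ship that made that hop,
whatever its history. Real ship movements are path-dependent — a ship that
reached Murmansk from Tromso may favour different next ports than one that
came from Narvik — so the higher-order network (HON) splits a port into
context-conditioned nodes ("Murmansk|Tromso") wherever the conditional
next-port distribution given the longer context differs enough from the
accepted lower-order one to justify the extra state.

Rule extraction keeps a higher-order context iff (a) its support reaches
``min_support`` and (b) the Kullback–Leibler divergence of its next-port
distribution from the accepted lower-order distribution exceeds
``divergence_threshold / (order × support)`` — the threshold shrinks as
support grows, so well-supported small deviations are kept. Accepted
contexts are extended recursively up to ``max_order``. Every physical port
retains its first-order rules, so the network has no dangling contexts.

Two weighting modes are supported: ``count`` (edge weight = number of
transitions, as in the worked example) and ``risk`` (edge weight = the
union-aggregated per-trip introduction risk of the transitions, the
species-flow variant). Round trips stay in the trajectory sequences (they
shape contexts) but never form edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .risk import Trip, aggregate_pathway_risk
from .voyage_data import ShipMovement, compute_duration

__all__ = [
    "Trajectory",
    "HONRule",
    "HONConfig",
    "build_trajectories",
    "build_fon",
    "extract_hon_rules",
    "build_sf_hon",
    "collapse_hon",
    "hon_label",
    "write_rules_csv",
    "read_rules_csv",
    "write_edgelist_csv",
    "write_graphml",
]


@dataclass(frozen=True)
class Trajectory:
    """A contiguous run of one ship's voyages: visited ports in temporal
    order, with the trip linking consecutive visits."""

    ship_id: str
    ports: tuple[str, ...]
    trips: tuple[Trip, ...]

    def __post_init__(self) -> None:
        if len(self.ports) != len(self.trips) + 1:
            raise ValueError("a trajectory of n trips visits n+1 ports")


@dataclass(frozen=True)
class HONRule:
    """Conditional movement rule: context (previous ports, most recent last)
    + current port → next port, with a count- or risk-mode weight."""

    context: tuple[str, ...]
    current: str
    next: str
    weight: float

    @property
    def order(self) -> int:
        return len(self.context) + 1


@dataclass
class HONConfig:
    """Extraction parameters.

    max_order            : longest dependency considered (default 5).
    min_support          : pruning threshold — transitions (count mode) or
                           aggregated probability (risk mode; 1e-3 is the
                           conventional non-trivial-pathway cut).
    divergence_threshold : scale of the KL acceptance test; the effective
                           threshold is divergence_threshold/(order×support).
    weighting            : "count" or "risk".
    """

    max_order: int = 5
    min_support: float = 1.0
    divergence_threshold: float = 25.0
    weighting: str = "count"

    def __post_init__(self) -> None:
        if self.max_order < 1:
            raise ValueError("max_order must be >= 1")
        if self.weighting not in ("count", "risk"):
            raise ValueError(f"unknown weighting mode {self.weighting!r}")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _as_trip(obj: Trip | ShipMovement) -> Trip:
    if isinstance(obj, Trip):
        return obj
    return Trip(movement=obj, delta=compute_duration(obj), discharge=0.0, risk=0.0)


def build_trajectories(trips: Sequence[Trip | ShipMovement]) -> list[Trajectory]:
    """Chain each ship's trips into contiguous trajectories.

    Visits are sorted by arrival date (ties: departure date, then input
    order). A discontinuity — the next trip not departing from the previous
    destination — starts a new trajectory, so contexts never span teleports.
    Bare movements are accepted for count-mode use (risk fields zeroed).
    """
    by_ship: dict[str, list[tuple] ] = {}
    for i, obj in enumerate(trips):
        t = _as_trip(obj)
        by_ship.setdefault(t.movement.ship_id, []).append(
            (t.movement.arrive_date, t.movement.depart_date, i, t))
    out: list[Trajectory] = []
    for ship_id in sorted(by_ship):
        seq = [t for *_k, t in sorted(by_ship[ship_id])]
        ports: list[str] = []
        legs: list[Trip] = []
        for t in seq:
            if ports and t.movement.origin != ports[-1]:
                out.append(Trajectory(ship_id, tuple(ports), tuple(legs)))
                ports, legs = [], []
            if not ports:
                ports.append(t.movement.origin)
            ports.append(t.movement.destination)
            legs.append(t)
        if legs:
            out.append(Trajectory(ship_id, tuple(ports), tuple(legs)))
    return out


# ---------------------------------------------------------------------------
# First-order network
# ---------------------------------------------------------------------------

def _combine(weighting: str, risks: Sequence[float]) -> float:
    if weighting == "count":
        return float(len(risks))
    return aggregate_pathway_risk(risks)


def build_fon(trajectories: Iterable[Trajectory],
              weighting: str = "count") -> nx.DiGraph:
    """First-order species-flow network; self-loops excluded."""
    pools: dict[tuple[str, str], list[float]] = {}
    g = nx.DiGraph(weighting=weighting)
    for tr in trajectories:
        for i, trip in enumerate(tr.trips):
            a, b = tr.ports[i], tr.ports[i + 1]
            if a == b:
                continue
            pools.setdefault((a, b), []).append(trip.risk)
            g.add_node(a, physical_port=a, context=())
            g.add_node(b, physical_port=b, context=())
    for (a, b), risks in pools.items():
        g.add_edge(a, b, weight=_combine(weighting, risks))
    return g


# ---------------------------------------------------------------------------
# Higher-order rule extraction
# ---------------------------------------------------------------------------

State = tuple[str, tuple[str, ...]]  # (current port, context)


def _kl_nats(ext: dict[str, float], low: dict[str, float]) -> float:
    total_e = sum(ext.values())
    total_l = sum(low.values())
    kl = 0.0
    for nxt, c in ext.items():
        p = c / total_e
        q = low.get(nxt, 0.0) / total_l
        if q == 0.0:
            return math.inf
        kl += p * math.log(p / q)
    return kl


def extract_hon_rules(trajectories: Sequence[Trajectory],
                      cfg: HONConfig = HONConfig()) -> list[HONRule]:
    """Extract variable-order movement rules from trajectories.

    Deterministic: no randomness anywhere in extraction. Each observed
    transition contributes weight to exactly one rule — the one with the
    longest accepted context matching its history — so collapsing the HON
    reproduces the FON exactly (flow conservation). Higher-order rules whose
    final weight falls below ``min_support`` hand their weight back to the
    parent rule rather than dropping flow.
    """
    trajectories = list(trajectories)
    # Phase 1: conditional next-port statistics for every context length
    counts: dict[State, dict[str, int]] = {}
    risks: dict[State, dict[str, list[float]]] = {}
    for tr in trajectories:
        seq = tr.ports
        for i, trip in enumerate(tr.trips):
            cur, nxt = seq[i], seq[i + 1]
            if cur == nxt:
                continue
            for order in range(1, cfg.max_order + 1):
                if i - (order - 1) < 0:
                    break
                st: State = (cur, tuple(seq[i - order + 1:i]))
                counts.setdefault(st, {})
                counts[st][nxt] = counts[st].get(nxt, 0) + 1
                risks.setdefault(st, {}).setdefault(nxt, []).append(trip.risk)

    # Phase 2: accept contexts whose distribution diverges from the parent's
    accepted: set[State] = {st for st in counts if not st[1]}
    for order in range(2, cfg.max_order + 1):
        for st in sorted(counts):
            cur, ctx = st
            if len(ctx) != order - 1:
                continue
            parent: State = (cur, ctx[1:])
            if parent not in accepted:
                continue
            support_n = sum(counts[st].values())
            support = (support_n if cfg.weighting == "count" else
                       aggregate_pathway_risk(
                           r for rs in risks[st].values() for r in rs))
            if support < cfg.min_support:
                continue
            kl = _kl_nats(counts[st], counts[parent])
            if kl > cfg.divergence_threshold / (order * support_n):
                accepted.add(st)

    # Phase 3: assign each transition to its longest accepted context
    rule_risks: dict[State, dict[str, list[float]]] = {}
    for tr in trajectories:
        seq = tr.ports
        for i, trip in enumerate(tr.trips):
            cur, nxt = seq[i], seq[i + 1]
            if cur == nxt:
                continue
            st = (cur, ())
            for order in range(min(cfg.max_order, i + 1), 1, -1):
                cand: State = (cur, tuple(seq[i - order + 1:i]))
                if cand in accepted:
                    st = cand
                    break
            rule_risks.setdefault(st, {}).setdefault(nxt, []).append(trip.risk)

    # Phase 4: prune under-supported higher-order rules upward, then emit
    for st in sorted(rule_risks, key=lambda s: len(s[1]), reverse=True):
        cur, ctx = st
        if not ctx:
            continue
        for nxt in list(rule_risks[st]):
            pool = rule_risks[st][nxt]
            if _combine(cfg.weighting, pool) < cfg.min_support:
                parent = (cur, ctx[1:])
                rule_risks.setdefault(parent, {}).setdefault(nxt, []).extend(pool)
                del rule_risks[st][nxt]
        if not rule_risks[st]:
            del rule_risks[st]

    rules = [
        HONRule(context=ctx, current=cur, next=nxt,
                weight=_combine(cfg.weighting, pool))
        for (cur, ctx), nexts in sorted(rule_risks.items())
        for nxt, pool in sorted(nexts.items())
    ]
    return rules


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def hon_label(node: State) -> str:
    """Render a (port, context) node as "Current|Prev1.Prev2"."""
    port, ctx = node
    return f"{port}|{'.'.join(ctx)}" if ctx else port


def build_sf_hon(rules: Sequence[HONRule]) -> nx.DiGraph:
    """Wire extracted rules into a network over (port, context) nodes.

    Each rule's edge targets the highest-order existing node for the next
    port whose context is a suffix of (rule context + current port) —
    standard longest-suffix wiring, so flow entering a port carries as much
    context forward as the rule set supports.
    """
    states: set[State] = {(r.current, r.context) for r in rules}
    by_edge = {(r.current, r.context, r.next) for r in rules}
    for r in rules:
        if r.context and not any(
                (r.context[-1], c, r.current) in by_edge
                for c in {s[1] for s in states}):
            raise ValueError(
                f"unreachable context in rule {hon_label((r.current, r.context))}"
                f" -> {r.next}: no rule moves {r.context[-1]} -> {r.current}")
    g = nx.DiGraph()
    for st in states:
        g.add_node(st, physical_port=st[0], context=st[1])
    for r in rules:
        src: State = (r.current, r.context)
        full = r.context + (r.current,)
        target: State | None = None
        for L in range(len(full), -1, -1):
            cand: State = (r.next, full[len(full) - L:])
            if cand in states:
                target = cand
                break
        if target is None:  # sink port never observed as current
            target = (r.next, ())
            g.add_node(target, physical_port=r.next, context=())
        g.add_edge(src, target, weight=r.weight)
    return g


def collapse_hon(hon: nx.DiGraph, weighting: str = "count") -> nx.DiGraph:
    """Merge context-conditioned nodes back to physical ports.

    Parallel edge weights are summed in count mode and probability-unioned
    in risk mode; a correct HON collapses to the FON of the same
    trajectories (flow conservation).
    """
    pools: dict[tuple[str, str], list[float]] = {}
    g = nx.DiGraph(weighting=weighting)
    for node, data in hon.nodes(data=True):
        g.add_node(data["physical_port"], physical_port=data["physical_port"],
                   context=())
    for u, v, data in hon.edges(data=True):
        a = hon.nodes[u]["physical_port"]
        b = hon.nodes[v]["physical_port"]
        pools.setdefault((a, b), []).append(data["weight"])
    for (a, b), ws in pools.items():
        if weighting == "count":
            g.add_edge(a, b, weight=float(sum(ws)))
        else:
            g.add_edge(a, b, weight=aggregate_pathway_risk(ws))
    return g


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def write_rules_csv(rules: Sequence[HONRule], path: str | Path,
                    header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "state": [hon_label((r.current, r.context)) for r in rules],
            "next": [r.next for r in rules],
            "weight": [r.weight for r in rules],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def read_rules_csv(path: str | Path) -> list[HONRule]:
    df = pd.read_csv(path, comment="#", dtype={"state": str, "next": str})
    rules: list[HONRule] = []
    for row in df.itertuples(index=False):
        if "|" in row.state:
            current, ctx_s = row.state.split("|", 1)
            context = tuple(ctx_s.split(".")) if ctx_s else ()
        else:
            current, context = row.state, ()
        rules.append(HONRule(context=context, current=current, next=str(row.next),
                             weight=float(row.weight)))
    return rules


def write_edgelist_csv(net: nx.DiGraph, path: str | Path,
                       header_lines: Sequence[str] = ()) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "source": _node_label(net, u),
            "target": _node_label(net, v),
            "weight": d["weight"],
        }
        for u, v, d in net.edges(data=True)
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
            fh, index=False)


def write_graphml(net: nx.DiGraph, path: str | Path) -> None:
    """GraphML export with string node ids and physical_port/context attrs."""
    relabel = {n: _node_label(net, n) for n in net.nodes}
    h = nx.DiGraph()
    for n, d in net.nodes(data=True):
        h.add_node(relabel[n], physical_port=d.get("physical_port", str(n)),
                   context=".".join(d.get("context", ())))
    for u, v, d in net.edges(data=True):
        h.add_edge(relabel[u], relabel[v], weight=float(d["weight"]))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(h, path)


def _node_label(net: nx.DiGraph, node: object) -> str:
    if isinstance(node, tuple):
        return hon_label(node)  # type: ignore[arg-type]
    return str(node)
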