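"""First-order and higher-order species-flow network construction."""

import datetime as dt

import numpy as np
import pytest

from ballastflow.flow_networks import (
    HONConfig,
    HONRule,
    build_fon,
    build_sf_hon,
    build_trajectories,
    collapse_hon,
    extract_hon_rules,
    read_rules_csv,
    write_rules_csv,
)
from ballastflow.risk import Trip
from ballastflow.synthetic import PlantedRule, SyntheticConfig, \
    generate_trajectories, generate_world
from ballastflow.voyage_data import ShipMovement


def mv(ship, origin, destination, day):
    return ShipMovement(ship_id=ship, ship_type_raw="x", gwt=1.0, dwt=1.0,
                        origin=origin, destination=destination,
                        depart_date=dt.date(2012, 1, 1) + dt.timedelta(days=day),
                        arrive_date=dt.date(2012, 1, 2) + dt.timedelta(days=day))


def synthetic_trajectories(seed=12, planted=True, n_ships=30, vpy=150):
    rules = []
    if planted:
        rules = [PlantedRule(context=("A000",), current="A001",
                             next_dist={"A002": 2 / 3, "A003": 1 / 3})]
    cfg = SyntheticConfig(n_arctic_ports=10, n_non_arctic_ports=0,
                          n_ships=n_ships, n_years=1, seed=seed,
                          route_concentration=0.0, planted_rules=rules,
                          voyages_per_ship_year=vpy)
    ports, _ = generate_world(cfg)
    return build_trajectories(generate_trajectories(cfg, ports))


class TestBuildTrajectories:
    def test_worked_fixture_shape(self, worked_trajectories):
        assert len(worked_trajectories) == 6
        assert all(len(t.ports) == 3 for t in worked_trajectories)

    def test_unordered_input_sorted(self):
        moves = [mv("S", "B", "C", 5), mv("S", "A", "B", 0)]
        (tr,) = build_trajectories(moves)
        assert tr.ports == ("A", "B", "C")

    def test_empty_input(self):
        assert build_trajectories([]) == []

    def test_discontinuity_splits(self):
        moves = [mv("S", "A", "B", 0), mv("S", "C", "D", 5)]
        trs = build_trajectories(moves)
        assert [t.ports for t in trs] == [("A", "B"), ("C", "D")]


class TestFon:
    def test_worked_fixture_counts(self, worked_trajectories):
        fon = build_fon(worked_trajectories, weighting="count")
        for a, b in [("Tromso", "Murmansk"), ("Narvik", "Murmansk"),
                     ("Murmansk", "Bodo"), ("Murmansk", "Nuuk")]:
            assert fon.edges[a, b]["weight"] == 3.0
        assert fon.number_of_edges() == 4

    def test_single_chain(self):
        fon = build_fon(build_trajectories([mv("S", "A", "B", 0),
                                            mv("S", "B", "C", 2)]))
        assert fon.edges["A", "B"]["weight"] == 1.0
        assert fon.edges["B", "C"]["weight"] == 1.0

    def test_risk_mode_single_transition(self):
        m = mv("S", "A", "B", 0)
        tr = build_trajectories([Trip(movement=m, delta=1.0, discharge=10.0,
                                      risk=0.37)])
        fon = build_fon(tr, weighting="risk")
        assert fon.edges["A", "B"]["weight"] == pytest.approx(0.37)

    def test_self_loops_excluded(self):
        fon = build_fon(build_trajectories([mv("S", "A", "A", 0),
                                            mv("S", "A", "B", 2)]))
        assert not fon.has_edge("A", "A") and fon.has_edge("A", "B")


class TestHonRules:
    def cfg(self, **kw):
        defaults = dict(max_order=2, min_support=1, divergence_threshold=0.0,
                        weighting="count")
        defaults.update(kw)
        return HONConfig(**defaults)

    def test_worked_fixture_rule_weights(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, self.cfg())
        w = {(r.context, r.current, r.next): r.weight for r in rules}
        assert w[(("Tromso",), "Murmansk", "Bodo")] == 2.0
        assert w[(("Tromso",), "Murmansk", "Nuuk")] == 1.0
        assert w[(("Narvik",), "Murmansk", "Bodo")] == 1.0
        assert w[(("Narvik",), "Murmansk", "Nuuk")] == 2.0

    def test_first_order_null_false_positive_rate(self):
        trajectories = synthetic_trajectories(seed=11, planted=False)
        rules = extract_hon_rules(trajectories, HONConfig(max_order=3))
        contexts = {(r.current, r.context) for r in rules if r.order >= 2}
        observed = set()
        for t in trajectories:
            for i in range(1, len(t.ports) - 1):
                observed.add((t.ports[i], (t.ports[i - 1],)))
        assert len(contexts) <= 0.05 * len(observed)

    def test_planted_rule_recovered_within_3se(self):
        trajectories = synthetic_trajectories(seed=12, planted=True)
        rules = extract_hon_rules(trajectories, HONConfig(max_order=3))
        state = [r for r in rules if r.current == "A001"
                 and r.context == ("A000",)]
        support = sum(r.weight for r in state)
        assert support > 10
        for nxt, p in (("A002", 2 / 3), ("A003", 1 / 3)):
            w = sum(r.weight for r in state if r.next == nxt)
            se = np.sqrt(p * (1 - p) / support)
            assert abs(w / support - p) <= 3 * se

    def test_min_support_monotone_pruning(self, worked_trajectories):
        trajectories = synthetic_trajectories(seed=12, planted=True)
        sets = []
        for ms in (1, 5, 20):
            rules = extract_hon_rules(trajectories,
                                      HONConfig(max_order=3, min_support=ms))
            sets.append({(r.context, r.current, r.next)
                         for r in rules if r.order >= 2})
        assert sets[2] <= sets[1] <= sets[0]

    def test_huge_min_support_leaves_first_order_only(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories,
                                  self.cfg(min_support=100))
        assert all(r.order == 1 for r in rules)

    def test_extraction_deterministic(self):
        trajectories = synthetic_trajectories(seed=12)
        cfg = HONConfig(max_order=3)
        assert extract_hon_rules(trajectories, cfg) == \
            extract_hon_rules(trajectories, cfg)

    def test_invalid_max_order(self):
        with pytest.raises(ValueError):
            HONConfig(max_order=0)


class TestHonNetwork:
    def test_worked_fixture_structure(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, HONConfig(
            max_order=2, min_support=1, divergence_threshold=0.0))
        hon = build_sf_hon(rules)
        mt, mn = ("Murmansk", ("Tromso",)), ("Murmansk", ("Narvik",))
        assert hon.has_node(mt) and hon.has_node(mn)
        assert hon.edges[mt, ("Bodo", ())]["weight"] == 2.0
        assert hon.edges[mt, ("Nuuk", ())]["weight"] == 1.0
        assert hon.edges[mn, ("Bodo", ())]["weight"] == 1.0
        assert hon.edges[mn, ("Nuuk", ())]["weight"] == 2.0

    def test_order1_equivalence_with_fon(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, HONConfig(max_order=1))
        hon = build_sf_hon(rules)
        fon = build_fon(worked_trajectories)
        assert {(u[0], v[0], d["weight"]) for u, v, d in hon.edges(data=True)} \
            == {(u, v, d["weight"]) for u, v, d in fon.edges(data=True)}

    def test_flow_conservation_count_mode(self):
        trajectories = synthetic_trajectories(seed=12, planted=True)
        rules = extract_hon_rules(trajectories, HONConfig(max_order=3))
        collapsed = collapse_hon(build_sf_hon(rules), weighting="count")
        fon = build_fon(trajectories, weighting="count")
        assert set(collapsed.edges) == set(fon.edges)
        for u, v in fon.edges:
            assert collapsed.edges[u, v]["weight"] == fon.edges[u, v]["weight"]

    def test_flow_conservation_risk_mode(self):
        rng = np.random.default_rng(8)
        trajectories = []
        for t in synthetic_trajectories(seed=12, planted=True, n_ships=10):
            trips = tuple(
                Trip(movement=tr.movement, delta=tr.delta, discharge=0.0,
                     risk=float(rng.uniform(0.0, 0.3))) for tr in t.trips)
            trajectories.append(type(t)(t.ship_id, t.ports, trips))
        rules = extract_hon_rules(
            trajectories, HONConfig(max_order=3, min_support=1e-3,
                                    weighting="risk"))
        collapsed = collapse_hon(build_sf_hon(rules), weighting="risk")
        fon = build_fon(trajectories, weighting="risk")
        assert set(collapsed.edges) == set(fon.edges)
        for u, v in fon.edges:
            assert collapsed.edges[u, v]["weight"] == pytest.approx(
                fon.edges[u, v]["weight"], abs=1e-9)

    def test_collapse_of_order1_hon_is_identity(self, worked_trajectories):
        rules = extract_hon_rules(worked_trajectories, HONConfig(max_order=1))
        hon = build_sf_hon(rules)
        collapsed = collapse_hon(hon)
        ports = {d["physical_port"] for _n, d in hon.nodes(data=True)}
        assert set(collapsed.nodes) == ports

    def test_empty_rules_empty_network(self):
        assert build_sf_hon([]).number_of_nodes() == 0

    def test_unreachable_context_rejected(self):
        rules = [HONRule(context=("Ghost",), current="A", next="B", weight=1.0),
                 HONRule(context=(), current="A", next="B", weight=1.0)]
        with pytest.raises(ValueError, match="Ghost"):
            build_sf_hon(rules)


class TestRulesCsv:
    def test_roundtrip(self, worked_trajectories, tmp_path):
        rules = extract_hon_rules(worked_trajectories, HONConfig(
            max_order=2, min_support=1, divergence_threshold=0.0))
        write_rules_csv(rules, tmp_path / "rules.csv", ["seed: 0"])
        assert read_rules_csv(tmp_path / "rules.csv") == sorted(
            rules, key=lambda r: (r.current, r.context, r.next))
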