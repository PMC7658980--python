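"""Pipeline orchestration: configuration, staged execution, artifact export.

Stages run in dependency order (simulate/ingest → discharge → risk → fon/hon
→ rank/cluster/propagate → trends → rewire → report). Every exported table
carries a provenance header (config hash, seed, stage) as ``#`` comment
lines, which the package's own readers skip; partial re-runs reuse cached
upstream CSV artifacts and fail with the name of the stage to run first when
one is missing.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import ballast as bl
from . import dispersal as dd
from . import evolution as ev
from . import flow_networks as fn
from . import risk as rk
from . import synthetic as syn
from . import voyage_data as vd

__all__ = ["PipelineConfig", "run_pipeline", "report_worked_example",
           "study_year", "STAGES"]

logger = logging.getLogger(__name__)

STAGES: tuple[str, ...] = (
    "simulate", "ingest", "discharge", "risk", "fon", "hon",
    "rank", "cluster", "propagate", "trends", "rewire", "report",
)


@dataclass
class PipelineConfig:
    """Run configuration; loadable from a single YAML file with overrides."""

    outdir: str = "out"
    seed: int = 0
    # input CSVs (written by `simulate` when absent)
    voyages_csv: str | None = None
    ballast_csv: str | None = None
    ports_csv: str | None = None
    adjacency_csv: str | None = None
    typemap_csv: str | None = None
    # model parameters
    risk_params: rk.RiskParams = field(default_factory=rk.RiskParams)
    hon: fn.HONConfig = field(default_factory=fn.HONConfig)
    walk: dd.WalkConfig = field(default_factory=dd.WalkConfig)
    tolerance_groups: Sequence[rk.ToleranceGroup] = rk.TOLERANCE_GROUPS
    synthetic: syn.SyntheticConfig = field(default_factory=syn.SyntheticConfig)
    projection_horizon: int = 15
    propagate_start: str | None = None
    propagate_steps: int = 3
    propagate_threshold: float = 0.0
    rewire_target: int | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        kwargs = dict(raw)
        if "risk_params" in kwargs:
            kwargs["risk_params"] = rk.RiskParams(**kwargs["risk_params"])
        if "hon" in kwargs:
            kwargs["hon"] = fn.HONConfig(**kwargs["hon"])
        if "walk" in kwargs:
            kwargs["walk"] = dd.WalkConfig(**kwargs["walk"])
        if "synthetic" in kwargs:
            kwargs["synthetic"] = syn.SyntheticConfig(**kwargs["synthetic"])
        return cls(**kwargs)

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, tuple):
                return list(o)
            return str(o)

        blob = json.dumps(dataclasses.asdict(self), default=enc, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def provenance(self, stage: str) -> list[str]:
        return [f"config_hash: {self.config_hash()}", f"seed: {self.seed}",
                f"stage: {stage}"]

    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def study_year(d: _dt.date) -> int:
    """Label a date with its study year (years run May 1 → Apr 30; the label
    is the starting calendar year)."""
    return d.year if d.month >= 5 else d.year - 1


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path.name}; run stage '{stage}' first")
    return path


def run_pipeline(cfg: PipelineConfig,
                 stages: Sequence[str] | None = None) -> dict[str, object]:
    """Execute the requested stages in dependency order; returns a dict of
    in-memory artifacts keyed by name."""
    logging.basicConfig(level=cfg.log_level)
    requested = list(STAGES) if stages is None else [
        s for s in STAGES if s in set(stages)]
    unknown = (set(stages or []) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    ctx: dict[str, object] = {}
    for stage in requested:
        _STAGE_FNS[stage](cfg, ctx)
    return ctx


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, ctx: dict) -> None:
    scfg = dataclasses.replace(cfg.synthetic, seed=cfg.seed)
    ports, adjacency = syn.generate_world(scfg)
    movements = syn.generate_trajectories(scfg, ports)
    fleet = [(syn.default_type_map()[m.ship_type_raw], m.gwt) for m in movements]
    records = syn.generate_ballast_records(scfg, fleet)
    hdr = cfg.provenance("simulate")
    vd.write_ports(ports.values(), cfg.path("ports.csv"), hdr)
    vd.write_ecoregion_adjacency(adjacency, cfg.path("adjacency.csv"), hdr)
    vd.write_voyages(movements, cfg.path("voyages.csv"), hdr)
    vd.write_ballast_records(records, cfg.path("ballast.csv"), hdr)
    syn.default_type_map().to_csv(cfg.path("typemap.csv"))
    ctx.update(ports=ports, adjacency=adjacency, movements=movements,
               ballast_records=records, typemap=syn.default_type_map())


def _load_inputs(cfg: PipelineConfig, ctx: dict) -> None:
    if "movements" in ctx:
        return
    ports_csv = Path(cfg.ports_csv or cfg.path("ports.csv"))
    voyages_csv = Path(cfg.voyages_csv or cfg.path("voyages.csv"))
    adjacency_csv = Path(cfg.adjacency_csv or cfg.path("adjacency.csv"))
    ballast_csv = Path(cfg.ballast_csv or cfg.path("ballast.csv"))
    typemap_csv = Path(cfg.typemap_csv or cfg.path("typemap.csv"))
    for p in (ports_csv, voyages_csv, adjacency_csv, ballast_csv, typemap_csv):
        _need(p, "simulate")
    ctx["ports"] = vd.read_ports(ports_csv)
    ctx["movements"] = vd.read_voyages(voyages_csv)
    ctx["adjacency"] = vd.read_ecoregion_adjacency(adjacency_csv)
    ctx["ballast_records"] = vd.read_ballast_records(ballast_csv)
    ctx["typemap"] = bl.TypeMap.from_csv(typemap_csv)


def _stage_ingest(cfg: PipelineConfig, ctx: dict) -> None:
    _load_inputs(cfg, ctx)
    movements = vd.deduplicate_movements(ctx["movements"])
    cl = vd.classify_voyages(movements, ctx["ports"])
    hdr = cfg.provenance("ingest")
    vd.write_voyages(cl.introduction, cfg.path("introduction_voyages.csv"), hdr)
    vd.write_voyages(cl.dispersal, cfg.path("dispersal_voyages.csv"), hdr)
    rej = pd.DataFrame(
        [{"reason": code, "detail": str(payload)} for code, payload in
         cl.rejections.entries], columns=["reason", "detail"])
    rej.to_csv(cfg.path("rejections.csv"), index=False)
    logger.info("ingest: %d movements in = %d introduction + %d dispersal + "
                "%d other + %d rejected",
                len(movements), len(cl.introduction), len(cl.dispersal),
                len(cl.other), cl.rejections.count())
    ctx["classified"] = cl


def _stage_discharge(cfg: PipelineConfig, ctx: dict) -> None:
    _load_inputs(cfg, ctx)
    records = ctx["ballast_records"]
    log = vd.RejectionLog()
    valid = vd.filter_ballast_records(records, log)
    Z = bl.estimate_discharge_frequency(valid, records)
    # types with a single valid record cannot support a per-type fit; they
    # fall back to the pooled estimate downstream
    counts: dict[str, int] = {}
    for r in valid:
        counts[r.vessel_type] = counts.get(r.vessel_type, 0) + 1
    fit_records = [r for r in valid if counts[r.vessel_type] >= 2]
    thin = sorted(k for k, n in counts.items() if n < 2)
    if thin:
        logger.warning("discharge: type(s) %s have <2 valid records; using "
                       "the pooled fallback for them", ", ".join(thin))
    reg = bl.fit_discharge_regression(fit_records, seed=cfg.seed)
    Z.to_csv(cfg.path("discharge_frequency.csv"))
    cfg.path("discharge_model.txt").write_text(
        "\n".join(cfg.provenance("discharge")
                  + [f"n_records: {len(records)}", f"n_valid: {len(valid)}",
                     f"dropped: {json.dumps(log.reasons())}",
                     f"test_r2: {reg.test_r2:.4f}"]) + "\n")
    ctx.update(Z=Z, regression=reg, valid_ballast=valid)


def _make_trips(cfg: PipelineConfig, ctx: dict,
                movements: list[vd.ShipMovement]) -> list[rk.Trip]:
    Z, reg, tm = ctx["Z"], ctx["regression"], ctx["typemap"]
    trips = []
    for m in movements:
        delta = vd.compute_duration(m)
        D = bl.estimate_trip_discharge(m, tm, Z, reg)
        trips.append(rk.Trip(movement=m, delta=delta, discharge=D,
                             risk=rk.per_trip_risk(D, delta, cfg.risk_params)))
    return trips


def _write_trips(trips: Sequence[rk.Trip], path: Path,
                 hdr: Sequence[str]) -> None:
    df = pd.DataFrame(
        {
            "ship_id": [t.movement.ship_id for t in trips],
            "origin": [t.movement.origin for t in trips],
            "destination": [t.movement.destination for t in trips],
            "year": [study_year(t.movement.depart_date) for t in trips],
            "delta": [t.delta for t in trips],
            "discharge": [t.discharge for t in trips],
            "risk": [t.risk for t in trips],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _write_pathways(pathways: Sequence[rk.Pathway], path: Path,
                    hdr: Sequence[str]) -> None:
    df = pd.DataFrame(
        {
            "source": [p.source for p in pathways],
            "target": [p.target for p in pathways],
            "risk": [p.risk for p in pathways],
            "n_trips": [p.n_trips for p in pathways],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in hdr:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _stage_risk(cfg: PipelineConfig, ctx: dict) -> None:
    if "classified" not in ctx:
        _stage_ingest(cfg, ctx)
    if "Z" not in ctx:
        _stage_discharge(cfg, ctx)
    cl = ctx["classified"]
    hdr = cfg.provenance("risk")
    for kind, movements in (("introduction", cl.introduction),
                            ("dispersal", cl.dispersal)):
        trips = _make_trips(cfg, ctx, movements)
        ctx[f"trips_{kind}"] = trips
        _write_trips(trips, cfg.path(f"trips_{kind}.csv"), hdr)
        pathways = rk.build_pathways(trips)
        if kind == "introduction":
            kept = vd.ecoregion_filter(pathways.keys(), ctx["ports"],
                                       ctx["adjacency"])
            pathways = {k: v for k, v in pathways.items() if k in kept}
        ctx[f"pathways_{kind}"] = pathways
        plist = sorted(pathways.values(), key=lambda p: (p.source, p.target))
        _write_pathways(plist, cfg.path(f"pathways_{kind}.csv"), hdr)
        # per-year pathway tables
        by_year: dict[int, list[rk.Trip]] = {}
        for t in trips:
            by_year.setdefault(study_year(t.movement.depart_date), []).append(t)
        for y, ts in sorted(by_year.items()):
            yearly = sorted(rk.build_pathways(ts).values(),
                            key=lambda p: (p.source, p.target))
            _write_pathways(yearly, cfg.path(f"pathways_{kind}_{y}.csv"), hdr)
        ctx[f"trips_{kind}_by_year"] = by_year
        # aggregated port risks
        incoming: dict[str, list[rk.Pathway]] = {}
        for p in pathways.values():
            incoming.setdefault(p.target, []).append(p)
        port_risks = [rk.aggregate_port_risk(ps) for ps in incoming.values()]
        pd.DataFrame({"port": [p.port for p in port_risks],
                      "risk": [p.risk for p in port_risks]}).sort_values(
            "risk", ascending=False).to_csv(
            cfg.path(f"port_risks_{kind}.csv"), index=False)
        ctx[f"port_risks_{kind}"] = port_risks
    # environmental tolerance filtering of introduction pathways
    intro = ctx["pathways_introduction"]
    for g in cfg.tolerance_groups:
        kept = rk.env_filter_pathways(intro.keys(), ctx["ports"], g)
        plist = sorted((intro[k] for k in kept),
                       key=lambda p: (p.source, p.target))
        _write_pathways(
            plist, cfg.path(f"pathways_introduction_dt{g.dt_max}_ds{g.ds_max}.csv"),
            hdr)


def _dispersal_trajectories(cfg: PipelineConfig, ctx: dict) -> list:
    if "trips_dispersal" not in ctx:
        _stage_risk(cfg, ctx)
    return fn.build_trajectories(ctx["trips_dispersal"])


def _stage_fon(cfg: PipelineConfig, ctx: dict) -> None:
    trajectories = _dispersal_trajectories(cfg, ctx)
    fon = fn.build_fon(trajectories, weighting=cfg.hon.weighting)
    ctx["fon"] = fon
    fn.write_edgelist_csv(fon, cfg.path("fon_edges.csv"), cfg.provenance("fon"))
    fn.write_graphml(fon, cfg.path("fon.graphml"))


def _stage_hon(cfg: PipelineConfig, ctx: dict) -> None:
    trajectories = _dispersal_trajectories(cfg, ctx)
    rules = fn.extract_hon_rules(trajectories, cfg.hon)
    hon = fn.build_sf_hon(rules)
    ctx.update(hon_rules=rules, hon=hon)
    fn.write_rules_csv(rules, cfg.path("hon_rules.csv"), cfg.provenance("hon"))
    fn.write_edgelist_csv(hon, cfg.path("hon_edges.csv"), cfg.provenance("hon"))
    fn.write_graphml(hon, cfg.path("hon.graphml"))


def _stage_rank(cfg: PipelineConfig, ctx: dict) -> None:
    if "fon" not in ctx:
        _stage_fon(cfg, ctx)
    if "hon" not in ctx:
        _stage_hon(cfg, ctx)
    table = dd.rank_direct_vs_indirect(ctx["fon"], ctx["hon"], cfg.walk)
    ctx["ranking"] = table
    with open(cfg.path("ranking.csv"), "w", encoding="utf-8", newline="") as fh:
        for line in cfg.provenance("rank"):
            fh.write(f"# {line}\n")
        table.to_csv(fh, index=False)


def _stage_cluster(cfg: PipelineConfig, ctx: dict) -> None:
    if "hon" not in ctx:
        _stage_hon(cfg, ctx)
    partition = dd.cluster_network(ctx["hon"], seed=cfg.seed)
    ctx["clusters"] = partition
    rows = [{"node": fn.hon_label(n) if isinstance(n, tuple) else str(n),
             "cluster": c} for n, c in sorted(partition.items(), key=lambda kv: str(kv[0]))]
    pd.DataFrame(rows).to_csv(cfg.path("clusters.csv"), index=False)


def _stage_propagate(cfg: PipelineConfig, ctx: dict) -> None:
    if "hon" not in ctx:
        _stage_hon(cfg, ctx)
    hon = ctx["hon"]
    start = cfg.propagate_start
    if start is None:  # default: the port with the largest out-strength
        strength: dict[str, float] = {}
        for u, _v, d in hon.edges(data=True):
            p = hon.nodes[u]["physical_port"]
            strength[p] = strength.get(p, 0.0) + d["weight"]
        start = max(sorted(strength), key=lambda p: strength[p])
    trace = dd.propagate_steps(hon, start, cfg.propagate_steps,
                               cfg.propagate_threshold)
    ctx["propagation"] = trace
    rows = [
        {"step": s + 1, "source": u, "target": v, "flow": w,
         "highlighted": w >= cfg.propagate_threshold}
        for s, step_flows in enumerate(trace.flows)
        for u, v, w in step_flows
    ]
    pd.DataFrame(rows, columns=["step", "source", "target", "flow",
                                "highlighted"]).to_csv(
        cfg.path("propagation.csv"), index=False)
    if "ports" in ctx:
        _propagation_geojson(trace, ctx["ports"], cfg.path("propagation.geojson"))


def _propagation_geojson(trace: dd.PropagationTrace, ports: dict,
                         path: Path) -> None:
    feats = []
    for s, reach in enumerate(trace.steps):
        for port, w in sorted(reach.items()):
            p = ports.get(port)
            if p is None:
                continue
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
                "properties": {"port": port, "step": s + 1, "reach": w},
            })
    path.write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=1))


def _stage_trends(cfg: PipelineConfig, ctx: dict) -> None:
    if "trips_introduction_by_year" not in ctx:
        _stage_risk(cfg, ctx)
    hdr = cfg.provenance("trends")
    all_rows, fit_rows, proj_rows = [], [], []
    for kind in ("introduction", "dispersal"):
        by_year = ctx[f"trips_{kind}_by_year"]
        pathways_by_year = {y: list(rk.build_pathways(ts).values())
                            for y, ts in by_year.items()}
        series = ev.compute_yearly_metrics(by_year, pathways_by_year)
        ctx[f"metrics_{kind}"] = series
        for s in series:
            for y, v in sorted(s.points.items()):
                all_rows.append({"kind": kind, "metric": s.metric_name,
                                 "year": y, "value": v})
            if len(s.points) >= 2:
                fit = ev.fit_trend(s)
                fit_rows.append({"kind": kind, "metric": s.metric_name,
                                 "slope": fit.slope, "intercept": fit.intercept,
                                 "p_value": fit.p_value,
                                 "slope_stderr": fit.slope_stderr})
                proj = ev.project_series(fit, cfg.projection_horizon)
                for row in proj.to_dict("records"):
                    proj_rows.append({"kind": kind, "metric": s.metric_name,
                                      **row})
                ctx[f"trend_{kind}_{s.metric_name}"] = fit
    for name, rows, cols in (
            ("metrics.csv", all_rows, ["kind", "metric", "year", "value"]),
            ("trends.csv", fit_rows, ["kind", "metric", "slope", "intercept",
                                      "p_value", "slope_stderr"]),
            ("projections.csv", proj_rows, None)):
        with open(cfg.path(name), "w", encoding="utf-8", newline="") as fh:
            for line in hdr:
                fh.write(f"# {line}\n")
            pd.DataFrame(rows, columns=cols).to_csv(fh, index=False)


def _stage_rewire(cfg: PipelineConfig, ctx: dict) -> None:
    if "pathways_introduction" not in ctx:
        _stage_risk(cfg, ctx)
    pathways = sorted(ctx["pathways_introduction"].values(),
                      key=lambda p: (p.source, p.target))
    if not pathways:
        logger.warning("rewire: no introduction pathways; skipping")
        return
    n_recipients = len({p.target for p in pathways})
    out_deg: dict[str, int] = {}
    for p in pathways:
        out_deg[p.source] = out_deg.get(p.source, 0) + 1
    feasible_min = max(out_deg.values())
    target = cfg.rewire_target
    if target is None:
        # default target from the fitted recipient-count trend at the horizon
        fit = ctx.get("trend_introduction_n_recipient_ports")
        if fit is not None:
            projected = fit.predict_mean(
                [fit.years[-1] + cfg.projection_horizon])[0]
            target = int(max(feasible_min, min(n_recipients, round(projected))))
        else:
            target = n_recipients
    rewired = ev.preferential_rewire(
        pathways, ev.RewireConfig(target_recipient_count=target, seed=cfg.seed))
    ctx["rewired"] = rewired
    _write_pathways(sorted(rewired, key=lambda p: (p.source, p.target)),
                    cfg.path("rewired_pathways.csv"), cfg.provenance("rewire"))


# ---------------------------------------------------------------------------
# Worked-example golden report
# ---------------------------------------------------------------------------

def report_worked_example() -> tuple[bool, str]:
    """Run the five-port example end-to-end and diff against the expected
    first-order weights, higher-order rule weights, transition rows and
    one-step propagation. Returns (all_ok, rendered report)."""
    movements = syn.worked_example_fixture()
    trajectories = fn.build_trajectories(movements)
    checks: list[tuple[str, object, object]] = []

    fon = fn.build_fon(trajectories, weighting="count")
    for (a, b) in [("Tromso", "Murmansk"), ("Narvik", "Murmansk"),
                   ("Murmansk", "Bodo"), ("Murmansk", "Nuuk")]:
        checks.append((f"FON weight {a}->{b}", 3.0,
                       fon.edges[a, b]["weight"] if fon.has_edge(a, b) else None))

    rules = fn.extract_hon_rules(trajectories, fn.HONConfig(
        max_order=2, min_support=1, divergence_threshold=0.0, weighting="count"))
    rw = {(r.context, r.current, r.next): r.weight for r in rules}
    for ctx_port, nxt, w in [("Tromso", "Bodo", 2.0), ("Tromso", "Nuuk", 1.0),
                             ("Narvik", "Bodo", 1.0), ("Narvik", "Nuuk", 2.0)]:
        checks.append((f"HON rule (Murmansk|{ctx_port})->{nxt}", w,
                       rw.get(((ctx_port,), "Murmansk", nxt))))

    hon = fn.build_sf_hon(rules)
    nodes_h, P_h, _ = dd.transition_matrix(hon)
    idx_h = {n: i for i, n in enumerate(nodes_h)}
    mt = ("Murmansk", ("Tromso",))
    for nxt, expect in [("Bodo", 2 / 3), ("Nuuk", 1 / 3)]:
        got = P_h[idx_h[mt], idx_h[(nxt, ())]] if mt in idx_h else None
        checks.append((f"HON transition (Murmansk|Tromso)->{nxt}", expect, got))

    nodes_f, P_f, _ = dd.transition_matrix(fon)
    idx_f = {n: i for i, n in enumerate(nodes_f)}
    for nxt, expect in [("Bodo", 0.5), ("Nuuk", 0.5)]:
        checks.append((f"FON transition Murmansk->{nxt}", expect,
                       P_f[idx_f["Murmansk"], idx_f[nxt]]))

    step1 = dd.propagate_steps(hon, mt, 1).steps[0]
    checks.append(("1-step propagation from Murmansk|Tromso",
                   {"Bodo": 2 / 3, "Nuuk": 1 / 3},
                   {k: round(v, 12) for k, v in sorted(step1.items())}))

    lines = [f"{'check':45s} {'expected':>22s} {'computed':>22s}  ok"]
    ok = True
    for name, expect, got in checks:
        good = _close(expect, got)
        ok &= good
        lines.append(f"{name:45s} {str(expect):>22s} {str(got):>22s}  "
                     f"{'PASS' if good else 'MISMATCH'}")
    lines.append(f"overall: {'PASS' if ok else 'FAIL'}")
    return ok, "\n".join(lines)


def _close(a: object, b: object, tol: float = 1e-9) -> bool:
    if isinstance(a, dict):
        return (isinstance(b, dict) and set(a) == set(b)
                and all(_close(a[k], b[k], tol) for k in a))
    if b is None:
        return False
    return abs(float(a) - float(b)) <= tol


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "ingest": _stage_ingest,
    "discharge": _stage_discharge,
    "risk": _stage_risk,
    "fon": _stage_fon,
    "hon": _stage_hon,
    "rank": _stage_rank,
    "cluster": _stage_cluster,
    "propagate": _stage_propagate,
    "trends": _stage_trends,
    "rewire": _stage_rewire,
    "report": lambda cfg, ctx: _stage_report(cfg, ctx),
}


def _stage_report(cfg: PipelineConfig, ctx: dict) -> None:
    ok, text = report_worked_example()
    cfg.path("worked_example_report.txt").write_text(text + "\n")
    ctx["report_ok"] = ok
    if not ok:
        raise RuntimeError("worked-example report found mismatches:\n" + text)
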