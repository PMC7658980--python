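"""Relative introduction-risk model: per-trip risk, pathway and port aggregation,
and environmental tolerance filtering.

The per-trip relative risk of species introduction for a voyage that
discharged ``D`` metric tons of ballast water over ``delta`` days is

    P = (1 - exp(-lambda * D)) * exp(-mu * delta)

with ``lambda`` the species introduction potential per unit discharge volume
(default 3.22e-6 per metric ton, calibrated so that P = 0.8 for a 500,000-ton
discharge on a zero-duration trip) and ``mu`` the daily in-ballast mortality
rate (default 0.02 per day). These are *relative* risks — the framework ranks
pathways and ports, it does not calibrate absolute introduction probabilities.

Trips on a pathway are treated as independent, so risks aggregate by the
union rule 1 - prod(1 - p); complement products are computed in log space so
risks down to ~1e-300 survive aggregation unflushed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product as _product
from typing import Iterable, Mapping, Sequence

from .voyage_data import Port, RejectionLog, ShipMovement

__all__ = [
    "RiskParams",
    "Trip",
    "Pathway",
    "PortRisk",
    "ToleranceGroup",
    "TOLERANCE_GROUPS",
    "per_trip_risk",
    "aggregate_pathway_risk",
    "aggregate_port_risk",
    "build_pathways",
    "env_filter_pathways",
    "normalize_outgoing",
]


@dataclass(frozen=True)
class RiskParams:
    """Parameters of the per-trip risk equation.

    lambda_ : species introduction potential per metric ton of discharge.
    mu      : daily species mortality rate during the voyage.
    """

    lambda_: float = 3.22e-6
    mu: float = 0.02

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")


@dataclass(frozen=True)
class Trip:
    """A voyage enriched with duration, estimated discharge and per-trip risk."""

    movement: ShipMovement
    delta: float
    discharge: float
    risk: float


@dataclass
class Pathway:
    """A directed port pair with union-aggregated risk over its trips."""

    source: str
    target: str
    risk: float
    n_trips: int
    trips: list[Trip] = field(default_factory=list)


@dataclass(frozen=True)
class PortRisk:
    port: str
    risk: float


@dataclass(frozen=True)
class ToleranceGroup:
    """Maximal tolerated |temperature| and |salinity| differences for a
    species tolerance class (deg C, ppt)."""

    dt_max: float
    ds_max: float

    def __post_init__(self) -> None:
        if self.dt_max <= 0 or self.ds_max <= 0:
            raise ValueError("tolerance bounds must be positive")


#: The six standard tolerance groups: thermal tolerance bounds for marine
#: invertebrates crossed with salinity bounds for freshwater-stenohaline,
#: marine-stenohaline and euryhaline species.
TOLERANCE_GROUPS: tuple[ToleranceGroup, ...] = tuple(
    ToleranceGroup(dt, ds) for dt, ds in _product((2.9, 9.7), (0.2, 2.0, 12.0))
)


def per_trip_risk(D: float, delta: float, params: RiskParams = RiskParams()) -> float:
    """Relative risk (1 - e^{-lambda D}) e^{-mu delta} of one trip.

    Strictly increasing in discharge ``D``, strictly decreasing in duration
    ``delta`` (for D > 0, mu > 0); exactly 0 when D = 0; always < 1.
    """
    if D < 0:
        raise ValueError(f"discharge must be non-negative, got {D}")
    if delta < 0:
        raise ValueError(f"duration must be non-negative, got {delta}")
    return -math.expm1(-params.lambda_ * D) * math.exp(-params.mu * delta)


def aggregate_pathway_risk(trip_risks: Iterable[float]) -> float:
    """Union probability 1 - prod(1 - p) of independent per-trip risks.

    Computed via a sum of log1p complements for numerical stability; an
    empty collection aggregates to 0.
    """
    log_comp = 0.0
    for p in trip_risks:
        if not 0.0 <= p < 1.0:
            raise ValueError(f"per-trip risk {p} outside [0, 1)")
        log_comp += math.log1p(-p)
    return -math.expm1(log_comp)


def build_pathways(trips: Sequence[Trip]) -> dict[tuple[str, str], Pathway]:
    """Group trips into directed pathways with union-aggregated risks.

    Round trips (origin == destination) never form a pathway: a self-loop is
    not a species transfer between ports.
    """
    groups: dict[tuple[str, str], list[Trip]] = {}
    for t in trips:
        if t.movement.is_round_trip:
            continue
        groups.setdefault((t.movement.origin, t.movement.destination), []).append(t)
    return {
        key: Pathway(
            source=key[0],
            target=key[1],
            risk=aggregate_pathway_risk(t.risk for t in ts),
            n_trips=len(ts),
            trips=ts,
        )
        for key, ts in groups.items()
    }


def aggregate_port_risk(incoming: Sequence[Pathway]) -> PortRisk:
    """Aggregated introduction risk of a target port over its distinct sources.

    P_j = 1 - prod_i (1 - P_{i->j}); all pathways must share the target.
    """
    if not incoming:
        raise ValueError("aggregate_port_risk requires at least one pathway")
    targets = {p.target for p in incoming}
    if len(targets) != 1:
        raise ValueError(f"pathways target multiple ports: {sorted(targets)}")
    sources = {p.source for p in incoming}
    if len(sources) != len(incoming):
        raise ValueError("duplicate source ports among incoming pathways")
    return PortRisk(port=incoming[0].target,
                    risk=aggregate_pathway_risk(p.risk for p in incoming))


def env_filter_pathways(
    pathways: Iterable[tuple[str, str]],
    ports: Mapping[str, Port],
    group: ToleranceGroup,
    log: RejectionLog | None = None,
) -> set[tuple[str, str]]:
    """Keep pathways whose endpoint environments lie within a tolerance group.

    A pathway (i, j) survives iff |temp_i - temp_j| <= dt_max and
    |sal_i - sal_j| <= ds_max. Monotone in the tolerance partial order: a
    looser group retains a superset of a stricter one. Pathways with a
    missing endpoint or environmental attribute are rejected and logged.
    """
    log = log if log is not None else RejectionLog()
    kept: set[tuple[str, str]] = set()
    for i, j in pathways:
        pi, pj = ports.get(i), ports.get(j)
        if pi is None or pj is None:
            log.reject("unknown_port", (i, j))
            continue
        if any(v is None or math.isnan(v)
               for v in (pi.temperature, pi.salinity, pj.temperature, pj.salinity)):
            log.reject("missing_environment", (i, j))
            continue
        if (abs(pi.temperature - pj.temperature) <= group.dt_max
                and abs(pi.salinity - pj.salinity) <= group.ds_max):
            kept.add((i, j))
    return kept


def normalize_outgoing(pathways: Sequence[Pathway]) -> dict[str, float]:
    """Out-edge probabilities of a random disperser at a port: risks of the
    outgoing pathways normalized to sum to 1."""
    if not pathways:
        raise ValueError("no outgoing pathways")
    sources = {p.source for p in pathways}
    if len(sources) != 1:
        raise ValueError(f"pathways leave multiple ports: {sorted(sources)}")
    total = sum(p.risk for p in pathways)
    if total <= 0:
        raise ValueError("all outgoing risks are zero; cannot normalize")
    return {p.target: p.risk / total for p in pathways}
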