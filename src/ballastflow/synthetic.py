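"""Synthetic voyage, ballast and port data with the statistical structure the
pipeline assumes.

The generator emulates the features of real shipping data that the analysis
depends on: heavy-tailed route-frequency distributions, vessel-type-dependent
discharge frequency, discharge volumes scaling with gross tonnage (with
multiplicative noise), positive trip durations, and — crucially for
higher-order network extraction — ship trajectories containing *planted*
second-order movement rules, where the next port depends on the previous port
and not just the current one. All outputs are pure functions of the config
(including its seed); each generator draws from an independent sub-stream so
modules can be regenerated in isolation.

It makes no attempt to reproduce real Arctic geography, real port names
(outside the worked-example fixture) or real traffic volumes.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .voyage_data import BallastRecord, EcoregionAdjacency, Port, ShipMovement
from .ballast import VESSEL_TYPES, TypeMap

__all__ = [
    "PlantedRule",
    "SyntheticConfig",
    "generate_world",
    "generate_trajectories",
    "generate_ballast_records",
    "planted_discharge",
    "default_type_map",
    "worked_example_fixture",
    "worked_example_ports",
]

# sub-stream tags so each generator has an independent RNG stream
_STREAM_WORLD, _STREAM_TRAJ, _STREAM_BALLAST = 11, 22, 33


@dataclass(frozen=True)
class PlantedRule:
    """A second-(or higher-)order movement rule: when a ship's recent history
    ends with ``context`` and it sits at ``current``, the next port is drawn
    from ``next_dist`` instead of the first-order kernel."""

    context: tuple[str, ...]
    current: str
    next_dist: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.next_dist.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"planted next-port distribution sums to {total}, not 1")


#: Default probability of a non-zero ballast release per vessel type,
#: loosely graded by how routinely each type ballasts/deballasts.
DEFAULT_DISCHARGE_FREQUENCY: dict[str, float] = {
    "bulker": 0.75, "tanker": 0.70, "general_cargo": 0.55, "container": 0.40,
    "roro": 0.35, "reefer": 0.45, "passenger": 0.20, "barge": 0.60,
    "other": 0.50,
}

#: Default per-type slope (tons discharged per ton of GWT) of the planted
#: piecewise-linear discharge curve.
DEFAULT_DISCHARGE_SCALE: dict[str, float] = {
    "bulker": 0.25, "tanker": 0.22, "general_cargo": 0.15, "container": 0.10,
    "roro": 0.08, "reefer": 0.12, "passenger": 0.05, "barge": 0.18,
    "other": 0.12,
}


@dataclass
class SyntheticConfig:
    """Study-condition parameters of the synthetic world.

    ``route_concentration`` is the Zipf exponent of port attractiveness
    (larger = heavier-tailed route frequencies); ``voyages_per_ship_year`` is
    the mean of the geometric trajectory-length distribution; ``noise_sd`` is
    the standard deviation of the multiplicative (lognormal) noise on
    discharge volumes.
    """

    n_arctic_ports: int = 12
    n_non_arctic_ports: int = 30
    n_ships: int = 50
    n_years: int = 1
    seed: int = 0
    route_concentration: float = 1.0
    planted_rules: list[PlantedRule] = field(default_factory=list)
    discharge_frequency: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISCHARGE_FREQUENCY))
    discharge_scale: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISCHARGE_SCALE))
    noise_sd: float = 0.10
    voyages_per_ship_year: float = 20.0
    start_year: int = 2008

    def __post_init__(self) -> None:
        if self.n_arctic_ports <= 0:
            raise ValueError("n_arctic_ports must be positive (an empty Arctic "
                             "leaves every downstream stage undefined)")
        if self.n_non_arctic_ports < 0 or self.n_ships <= 0 or self.n_years <= 0:
            raise ValueError("counts must be positive")
        for k, p in self.discharge_frequency.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"discharge_frequency[{k}] = {p} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


# ---------------------------------------------------------------------------
# World
# ---------------------------------------------------------------------------

def generate_world(cfg: SyntheticConfig) -> tuple[dict[str, Port], EcoregionAdjacency]:
    """Generate the port table and ecoregion adjacency.

    Arctic ports sit at high latitude; water temperature decreases with
    latitude plus noise; salinities mix marine (~32-35 ppt) and
    brackish/fresh (<5 ppt) ports; ecoregions are longitude-sector blocks
    split by the Arctic boundary, with adjacent sectors in the same band
    declared neighbors.
    """
    rng = cfg.rng(_STREAM_WORLD)
    ports: dict[str, Port] = {}

    def _make(port_id: str, arctic: bool) -> Port:
        lat = float(rng.uniform(67.0, 80.0) if arctic else rng.uniform(10.0, 60.0))
        lon = float(rng.uniform(-180.0, 180.0))
        temp = float(25.0 - 0.32 * lat + rng.normal(0.0, 1.5))
        if rng.random() < 0.15:  # brackish/fresh (estuarine or river) port
            sal = float(rng.uniform(0.0, 5.0))
        else:
            sal = float(np.clip(rng.normal(33.5, 1.0), 30.0, 36.0))
        sector = int((lon + 180.0) // 60.0)  # 6 longitude blocks
        band = "AR" if arctic else "LO"
        return Port(port_id=port_id, name=port_id, lat=lat, lon=lon,
                    is_arctic=arctic, ecoregion_id=f"{band}{sector}",
                    temperature=temp, salinity=sal)

    for i in range(cfg.n_arctic_ports):
        p = _make(f"A{i:03d}", True)
        ports[p.port_id] = p
    for i in range(cfg.n_non_arctic_ports):
        p = _make(f"N{i:03d}", False)
        ports[p.port_id] = p

    adjacency = EcoregionAdjacency()
    for band in ("AR", "LO"):
        for s in range(6):
            adjacency.add(f"{band}{s}", f"{band}{(s + 1) % 6}")
    return ports, adjacency


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

_RAW_TYPES: dict[str, str] = {
    # a coarse stand-in for a many-category source taxonomy
    "Bulk Carrier": "bulker", "Ore Carrier": "bulker",
    "Container Ship": "container", "Cellular Container": "container",
    "General Cargo": "general_cargo", "Multi-Purpose": "general_cargo",
    "Cruise Ship": "passenger", "Ferry": "passenger",
    "Refrigerated Cargo": "reefer",
    "Vehicle Carrier": "roro", "Ro-Ro Cargo": "roro",
    "Crude Oil Tanker": "tanker", "Chemical Tanker": "tanker",
    "Products Tanker": "tanker",
    "Deck Barge": "barge", "Hopper Barge": "barge",
    "Research Vessel": "other", "Supply Vessel": "other", "Tug": "other",
}


def default_type_map() -> TypeMap:
    """Map from the synthetic raw ship-type labels to the 9-category taxonomy."""
    return TypeMap(dict(_RAW_TYPES))


def generate_trajectories(
    cfg: SyntheticConfig, ports: dict[str, Port]
) -> list[ShipMovement]:
    """Simulate ship voyage sequences.

    Next-port choice follows a first-order kernel whose stationary route
    frequencies are heavy-tailed (port attractiveness ~ Zipf with exponent
    ``route_concentration``), except where a planted rule's context matches
    the ship's recent history, in which case the next port is drawn from the
    rule's distribution. Trajectory lengths are geometric with mean
    ``voyages_per_ship_year`` voyages per ship-year.
    """
    rng = cfg.rng(_STREAM_TRAJ)
    port_ids = sorted(ports)
    n = len(port_ids)
    if n < 2:
        raise ValueError("need at least two ports to generate voyages")

    # Zipf attractiveness over a random permutation of ports
    ranks = rng.permutation(n) + 1
    attract = ranks.astype(float) ** (-cfg.route_concentration)
    attract /= attract.sum()
    idx = {p: i for i, p in enumerate(port_ids)}

    raw_labels = sorted(_RAW_TYPES)
    movements: list[ShipMovement] = []
    for s in range(cfg.n_ships):
        ship_id = f"S{s:04d}"
        gwt = float(10 ** rng.uniform(3.0, 5.0))
        dwt = float(gwt * rng.uniform(0.55, 0.75))
        raw_type = raw_labels[int(rng.integers(len(raw_labels)))]
        for y in range(cfg.n_years):
            date = _dt.date(cfg.start_year + y, 5, 1) + _dt.timedelta(
                days=int(rng.integers(0, 30)))
            p_mean = 1.0 / max(cfg.voyages_per_ship_year, 1.0)
            n_voyages = int(rng.geometric(p_mean))
            current = port_ids[int(rng.choice(n, p=attract))]
            history: list[str] = []
            for _ in range(n_voyages):
                nxt = _draw_next(rng, cfg, current, history, port_ids, attract, idx)
                duration = int(rng.integers(1, 15))
                depart = date
                arrive = depart + _dt.timedelta(days=duration)
                movements.append(ShipMovement(
                    ship_id=ship_id, ship_type_raw=raw_type, gwt=gwt, dwt=dwt,
                    origin=current, destination=nxt,
                    depart_date=depart, arrive_date=arrive))
                date = arrive + _dt.timedelta(days=int(rng.integers(1, 4)))
                history.append(current)
                current = nxt
    return movements


def _draw_next(rng, cfg, current, history, port_ids, attract, idx):
    for rule in cfg.planted_rules:
        c = len(rule.context)
        if (rule.current == current and c <= len(history)
                and tuple(history[-c:]) == rule.context):
            targets = sorted(rule.next_dist)
            probs = np.array([rule.next_dist[t] for t in targets])
            return targets[int(rng.choice(len(targets), p=probs))]
    w = attract.copy()
    w[idx[current]] = 0.0  # no self-loops in the background kernel
    w /= w.sum()
    return port_ids[int(rng.choice(len(port_ids), p=w))]


# ---------------------------------------------------------------------------
# Ballast records
# ---------------------------------------------------------------------------

def planted_discharge(vessel_type: str, gwt: float,
                      cfg: SyntheticConfig) -> float:
    """Ground-truth conditional discharge volume: piecewise-linear in GWT.

    Full slope up to 30,000 tons GWT, 30% of the slope beyond (large ships
    discharge proportionally less of their tonnage).
    """
    c = cfg.discharge_scale[vessel_type]
    knee = 30_000.0
    return c * min(gwt, knee) + 0.3 * c * max(0.0, gwt - knee)


def generate_ballast_records(
    cfg: SyntheticConfig, fleet: Sequence[tuple[str, float]]
) -> list[BallastRecord]:
    """Generate one ballast report per fleet visit (vessel_type, gwt).

    Discharge is zero with probability 1 - discharge_frequency[type], else
    the planted per-type curve of GWT times multiplicative lognormal noise,
    capped at capacity (half the GWT).
    """
    rng = cfg.rng(_STREAM_BALLAST)
    out: list[BallastRecord] = []
    for vessel_type, gwt in fleet:
        capacity = 0.5 * gwt
        if rng.random() >= cfg.discharge_frequency[vessel_type]:
            discharge = 0.0
        else:
            base = planted_discharge(vessel_type, gwt, cfg)
            noise = float(rng.lognormal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 1.0
            discharge = min(capacity, base * noise)
        out.append(BallastRecord(vessel_type=vessel_type, gwt=float(gwt),
                                 discharge=float(discharge),
                                 capacity=float(capacity)))
    return out


# ---------------------------------------------------------------------------
# Worked example (five named ports, six two-leg trajectories)
# ---------------------------------------------------------------------------

_FIXTURE_LEGS: list[tuple[str, str, str]] = (
    [("Tromso", "Murmansk", "Bodo")] * 2
    + [("Tromso", "Murmansk", "Nuuk")]
    + [("Narvik", "Murmansk", "Bodo")]
    + [("Narvik", "Murmansk", "Nuuk")] * 2
)


def worked_example_fixture() -> list[ShipMovement]:
    """Six two-leg ship trajectories over {Tromso, Narvik, Murmansk, Bodo, Nuuk}.

    Tromso→Murmansk→Bodo ×2, Tromso→Murmansk→Nuuk ×1,
    Narvik→Murmansk→Bodo ×1, Narvik→Murmansk→Nuuk ×2 — the unique assignment
    under which every port-pair carries exactly three trips while ships from
    Tromso favour Bodo (2:1) and ships from Narvik favour Nuuk (1:2).
    Twelve movements in all (6 ships × 2 legs).
    """
    movements: list[ShipMovement] = []
    base = _dt.date(2012, 5, 1)
    for s, (a, b, c) in enumerate(_FIXTURE_LEGS):
        d0 = base + _dt.timedelta(days=10 * s)
        common = dict(ship_id=f"EX{s}", ship_type_raw="General Cargo",
                      gwt=20_000.0, dwt=12_000.0)
        movements.append(ShipMovement(origin=a, destination=b, depart_date=d0,
                                      arrive_date=d0 + _dt.timedelta(days=2),
                                      **common))
        movements.append(ShipMovement(origin=b, destination=c,
                                      depart_date=d0 + _dt.timedelta(days=3),
                                      arrive_date=d0 + _dt.timedelta(days=5),
                                      **common))
    return movements


def worked_example_ports() -> dict[str, Port]:
    """Port table for the worked example.

    Coordinates are approximately real; ecoregion and environmental
    attributes are synthetic placeholders (the example exercises network
    construction, not environmental filtering).
    """
    rows = [
        ("Tromso", 69.6, 18.9), ("Narvik", 68.4, 17.4), ("Murmansk", 68.9, 33.1),
        ("Bodo", 67.3, 14.4), ("Nuuk", 64.2, -51.7),
    ]
    return {
        name: Port(port_id=name, name=name, lat=lat, lon=lon, is_arctic=True,
                   ecoregion_id=f"EX{i}", temperature=4.0, salinity=33.0)
        for i, (name, lat, lon) in enumerate(rows)
    }
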