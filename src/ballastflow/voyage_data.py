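"""Domain data model and ingestion for ship-movement and ballast-discharge records.

The atomic inputs of the pipeline are individual voyage records (one ship
sailing from an origin port to a destination port on known dates), ballast
discharge reports from a clearinghouse-style survey, a port table carrying
geographic, biogeographic (ecoregion) and environmental (temperature,
salinity) attributes, and an ecoregion adjacency relation used to exclude
transfers that could plausibly happen by natural dispersal.

All record rejections are collected in a :class:`RejectionLog` with
machine-readable reason codes; nothing is silently dropped.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Port",
    "ShipMovement",
    "BallastRecord",
    "EcoregionAdjacency",
    "RejectionLog",
    "VoyageClassification",
    "deduplicate_movements",
    "compute_duration",
    "classify_voyages",
    "ecoregion_filter",
    "filter_ballast_records",
    "read_ports",
    "read_voyages",
    "read_ballast_records",
    "read_ecoregion_adjacency",
    "write_ports",
    "write_voyages",
    "write_ballast_records",
    "write_ecoregion_adjacency",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Port:
    """A port with geographic, biogeographic and environmental attributes.

    ``is_arctic`` marks membership of the Arctic conservation-area boundary
    (a per-port boolean supplied by the data, not a polygon test; see
    :func:`arctic_flags_from_polygon` for users who carry a boundary polygon).
    ``temperature`` is the annual mean water temperature in deg C and
    ``salinity`` the annual mean salinity in ppt.
    """

    port_id: str
    name: str
    lat: float
    lon: float
    is_arctic: bool
    ecoregion_id: str
    temperature: float
    salinity: float

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"latitude {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise ValueError(f"longitude {self.lon} outside [-180, 180]")
        if self.salinity < 0:
            raise ValueError(f"salinity {self.salinity} < 0")
        if not self.ecoregion_id:
            raise ValueError("ecoregion_id must be non-empty")


@dataclass(frozen=True)
class ShipMovement:
    """One voyage record: who, what ship, where from/to, when."""

    ship_id: str
    ship_type_raw: str
    gwt: float
    dwt: float
    origin: str
    destination: str
    depart_date: _dt.date
    arrive_date: _dt.date

    def __post_init__(self) -> None:
        if self.arrive_date < self.depart_date:
            raise ValueError(
                f"arrival {self.arrive_date} precedes departure {self.depart_date}"
            )
        if self.gwt <= 0:
            raise ValueError(f"gwt must be positive, got {self.gwt}")

    @property
    def is_round_trip(self) -> bool:
        return self.origin == self.destination


@dataclass(frozen=True)
class BallastRecord:
    """One ballast discharge report (vessel type, tonnage, discharge, capacity)."""

    vessel_type: str | None
    gwt: float | None
    discharge: float | None
    capacity: float | None

    @property
    def is_valid(self) -> bool:
        """True iff no field is missing, discharge > 0 and discharge <= capacity."""
        if any(v is None for v in (self.vessel_type, self.gwt, self.discharge, self.capacity)):
            return False
        return self.discharge > 0 and self.discharge <= self.capacity


class EcoregionAdjacency:
    """Symmetric, reflexive 'neighboring ecoregions' relation.

    The relation is supplied explicitly (the operational definition of
    "neighboring" is a data question, not guessed here); it is made symmetric
    and reflexive by construction.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()) -> None:
        self._pairs: set[frozenset[str]] = set()
        self._regions: set[str] = set()
        for a, b in pairs:
            self.add(a, b)

    def add(self, a: str, b: str) -> None:
        self._pairs.add(frozenset((a, b)))
        self._regions.update((a, b))

    def neighbors(self, a: str, b: str) -> bool:
        """True if the two regions are identical or declared neighbors."""
        return a == b or frozenset((a, b)) in self._pairs

    @property
    def pairs(self) -> set[frozenset[str]]:
        return set(self._pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.neighbors(*pair)


# ---------------------------------------------------------------------------
# Rejection logging
# ---------------------------------------------------------------------------

@dataclass
class RejectionLog:
    """Machine-readable record of every dropped record/pathway."""

    entries: list[tuple[str, object]] = field(default_factory=list)

    def reject(self, reason_code: str, payload: object) -> None:
        self.entries.append((reason_code, payload))

    def count(self, reason_code: str | None = None) -> int:
        if reason_code is None:
            return len(self.entries)
        return sum(1 for code, _ in self.entries if code == reason_code)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for code, _ in self.entries:
            out[code] = out.get(code, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def deduplicate_movements(movements: Sequence[ShipMovement]) -> list[ShipMovement]:
    """Remove exact duplicate voyage records, keeping first occurrences in order."""
    seen: set[ShipMovement] = set()
    out: list[ShipMovement] = []
    for m in movements:
        if m not in seen:
            seen.add(m)
            out.append(m)
    return out


def compute_duration(m: ShipMovement, log: RejectionLog | None = None) -> float:
    """Trip duration in days (arrival minus departure); never negative.

    A negative duration cannot occur for a validated :class:`ShipMovement`,
    but raw tuples routed here are rejected and logged.
    """
    delta = (m.arrive_date - m.depart_date).days
    if delta < 0:
        if log is not None:
            log.reject("negative_duration", m)
        raise ValueError(f"negative duration for movement {m}")
    return float(delta)


@dataclass
class VoyageClassification:
    """Partition of voyages into introduction / dispersal / other sets."""

    introduction: list[ShipMovement]
    dispersal: list[ShipMovement]
    other: list[ShipMovement]
    rejections: RejectionLog


def classify_voyages(
    movements: Sequence[ShipMovement], ports: dict[str, Port]
) -> VoyageClassification:
    """Split voyages into introduction (non-Arctic → Arctic), dispersal
    (Arctic → Arctic) and other pathway classes.

    Movements referencing an unknown port are rejected and logged; the three
    returned sets partition the accepted input.
    """
    intro: list[ShipMovement] = []
    disp: list[ShipMovement] = []
    other: list[ShipMovement] = []
    log = RejectionLog()
    for m in movements:
        o = ports.get(m.origin)
        d = ports.get(m.destination)
        if o is None or d is None:
            log.reject("unknown_port", m)
            continue
        if d.is_arctic and not o.is_arctic:
            intro.append(m)
        elif d.is_arctic and o.is_arctic:
            disp.append(m)
        else:
            other.append(m)
    return VoyageClassification(intro, disp, other, log)


def ecoregion_filter(
    pathways: Iterable[tuple[str, str]],
    ports: dict[str, Port],
    adjacency: EcoregionAdjacency,
    log: RejectionLog | None = None,
) -> set[tuple[str, str]]:
    """Drop port pairs within the same or neighboring ecoregions.

    Species could plausibly reach same- or neighboring-ecoregion ports by
    natural dispersal, so those pathways are not counted as ship-mediated
    introductions. Idempotent: filtering a filtered set is a no-op.
    """
    log = log if log is not None else RejectionLog()
    kept: set[tuple[str, str]] = set()
    for i, j in pathways:
        pi, pj = ports.get(i), ports.get(j)
        if pi is None or pj is None:
            log.reject("unknown_port", (i, j))
            continue
        if adjacency.neighbors(pi.ecoregion_id, pj.ecoregion_id):
            log.reject("same_or_neighboring_ecoregion", (i, j))
            continue
        kept.add((i, j))
    return kept


def filter_ballast_records(
    records: Sequence[BallastRecord], log: RejectionLog | None = None
) -> list[BallastRecord]:
    """Keep only valid ballast records.

    Invalid means missing fields, zero discharge, or discharge exceeding
    capacity; invalid records are dropped and counted in the log.
    """
    log = log if log is not None else RejectionLog()
    out: list[BallastRecord] = []
    for r in records:
        if r.is_valid:
            out.append(r)
        elif any(v is None for v in (r.vessel_type, r.gwt, r.discharge, r.capacity)):
            log.reject("missing_field", r)
        elif r.discharge == 0:
            log.reject("zero_discharge", r)
        else:
            log.reject("discharge_exceeds_capacity", r)
    return out


def arctic_flags_from_polygon(
    ports: Iterable[Port], polygon: Sequence[tuple[float, float]]
) -> dict[str, bool]:
    """Optional hook: derive ``is_arctic`` flags from a boundary polygon.

    ``polygon`` is a sequence of (lon, lat) vertices. Ports on the boundary
    count as Arctic. Requires shapely only when called.
    """
    from shapely.geometry import Point, Polygon

    poly = Polygon(polygon)
    return {
        p.port_id: bool(poly.covers(Point(p.lon, p.lat)))  # covers: boundary included
        for p in ports
    }


# ---------------------------------------------------------------------------
# CSV I/O — the canonical dialects of the pipeline
# ---------------------------------------------------------------------------

_VOYAGE_COLS = ["ship_id", "ship_type", "gwt", "dwt", "origin", "destination",
                "depart_date", "arrive_date"]
_BALLAST_COLS = ["vessel_type", "gwt", "discharge", "capacity"]
_PORT_COLS = ["port_id", "name", "lat", "lon", "is_arctic", "ecoregion_id",
              "temperature", "salinity"]
_ADJ_COLS = ["region_a", "region_b"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file missing required column(s): {', '.join(missing)}")


def read_voyages(path: str | Path, log: RejectionLog | None = None) -> list[ShipMovement]:
    """Read voyage records from CSV; extra columns tolerated, invalid rows logged."""
    log = log if log is not None else RejectionLog()
    df = pd.read_csv(path, comment="#", dtype={"ship_id": str, "origin": str,
                                               "destination": str, "ship_type": str})
    _require_columns(df, _VOYAGE_COLS, "voyage")
    out: list[ShipMovement] = []
    for row in df.itertuples(index=False):
        try:
            out.append(
                ShipMovement(
                    ship_id=str(row.ship_id),
                    ship_type_raw=str(row.ship_type),
                    gwt=float(row.gwt),
                    dwt=float(row.dwt),
                    origin=str(row.origin),
                    destination=str(row.destination),
                    depart_date=_dt.date.fromisoformat(str(row.depart_date)),
                    arrive_date=_dt.date.fromisoformat(str(row.arrive_date)),
                )
            )
        except (ValueError, TypeError) as exc:
            log.reject("invalid_voyage_row", (tuple(row), str(exc)))
    return out


def write_voyages(movements: Sequence[ShipMovement], path: str | Path,
                  header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "ship_id": [m.ship_id for m in movements],
            "ship_type": [m.ship_type_raw for m in movements],
            "gwt": [m.gwt for m in movements],
            "dwt": [m.dwt for m in movements],
            "origin": [m.origin for m in movements],
            "destination": [m.destination for m in movements],
            "depart_date": [m.depart_date.isoformat() for m in movements],
            "arrive_date": [m.arrive_date.isoformat() for m in movements],
        }
    )
    _write_with_header(df, path, header_lines)


def read_ports(path: str | Path) -> dict[str, Port]:
    df = pd.read_csv(path, comment="#", dtype={"port_id": str, "ecoregion_id": str})
    _require_columns(df, _PORT_COLS, "port")
    ports: dict[str, Port] = {}
    for row in df.itertuples(index=False):
        p = Port(
            port_id=str(row.port_id),
            name=str(row.name),
            lat=float(row.lat),
            lon=float(row.lon),
            is_arctic=_to_bool(row.is_arctic),
            ecoregion_id=str(row.ecoregion_id),
            temperature=float(row.temperature),
            salinity=float(row.salinity),
        )
        ports[p.port_id] = p
    return ports


def write_ports(ports: Iterable[Port], path: str | Path,
                header_lines: Sequence[str] = ()) -> None:
    ports = list(ports)
    df = pd.DataFrame(
        {
            "port_id": [p.port_id for p in ports],
            "name": [p.name for p in ports],
            "lat": [p.lat for p in ports],
            "lon": [p.lon for p in ports],
            "is_arctic": [p.is_arctic for p in ports],
            "ecoregion_id": [p.ecoregion_id for p in ports],
            "temperature": [p.temperature for p in ports],
            "salinity": [p.salinity for p in ports],
        }
    )
    _write_with_header(df, path, header_lines)


def read_ballast_records(path: str | Path) -> list[BallastRecord]:
    df = pd.read_csv(path, comment="#", dtype={"vessel_type": str})
    _require_columns(df, _BALLAST_COLS, "ballast")
    out: list[BallastRecord] = []
    for row in df.itertuples(index=False):
        out.append(
            BallastRecord(
                vessel_type=None if pd.isna(row.vessel_type) else str(row.vessel_type),
                gwt=None if pd.isna(row.gwt) else float(row.gwt),
                discharge=None if pd.isna(row.discharge) else float(row.discharge),
                capacity=None if pd.isna(row.capacity) else float(row.capacity),
            )
        )
    return out


def write_ballast_records(records: Sequence[BallastRecord], path: str | Path,
                          header_lines: Sequence[str] = ()) -> None:
    df = pd.DataFrame(
        {
            "vessel_type": [r.vessel_type for r in records],
            "gwt": [r.gwt for r in records],
            "discharge": [r.discharge for r in records],
            "capacity": [r.capacity for r in records],
        }
    )
    _write_with_header(df, path, header_lines)


def read_ecoregion_adjacency(path: str | Path) -> EcoregionAdjacency:
    df = pd.read_csv(path, comment="#", dtype=str)
    _require_columns(df, _ADJ_COLS, "ecoregion adjacency")
    return EcoregionAdjacency((str(r.region_a), str(r.region_b))
                              for r in df.itertuples(index=False))


def write_ecoregion_adjacency(adj: EcoregionAdjacency, path: str | Path,
                              header_lines: Sequence[str] = ()) -> None:
    rows = sorted(tuple(sorted(p)) for p in adj.pairs)
    df = pd.DataFrame(rows or [], columns=_ADJ_COLS)
    _write_with_header(df, path, header_lines)


def _write_with_header(df: pd.DataFrame, path: str | Path,
                       header_lines: Sequence[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def _to_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    if isinstance(v, (int, float)):
        return bool(v)
    return str(v).strip().lower() in {"true", "1", "yes", "t"}
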