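"""Ballast-water discharge estimation.

The expected discharge of a voyage is modelled as a hurdle: a ship of type
``k`` discharges at all with probability ``Z_k`` (the fraction of non-zero
releases observed for that type in clearinghouse data), and, conditional on
discharging, releases ``W_GWT`` metric tons predicted by a regression of
discharge on (vessel type, gross weight tonnage) fitted to the non-zero
records only. The per-voyage expectation is ``D = Z_k * W_GWT``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import r2_score
from sklearn.model_selection import train_test_split

from .voyage_data import BallastRecord, ShipMovement

__all__ = [
    "VESSEL_TYPES",
    "DischargeFrequencyTable",
    "DischargeRegression",
    "TypeMap",
    "estimate_discharge_frequency",
    "fit_discharge_regression",
    "estimate_trip_discharge",
]

logger = logging.getLogger(__name__)

#: The 9-category vessel taxonomy of the ballast clearinghouse data.
VESSEL_TYPES: tuple[str, ...] = (
    "bulker", "container", "general_cargo", "passenger", "reefer",
    "roro", "tanker", "barge", "other",
)

#: Key under which the pooled (all types) fallback estimate is stored.
POOLED = "__pooled__"


@dataclass
class DischargeFrequencyTable:
    """Per-type fraction Z_k of non-zero ballast releases."""

    Z: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.Z.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"Z[{k}] = {v} outside [0, 1]")

    def __getitem__(self, vessel_type: str) -> float:
        return self.Z[vessel_type]

    def __contains__(self, vessel_type: str) -> bool:
        return vessel_type in self.Z

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.Z.items()), columns=["type", "Z_k"]).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DischargeFrequencyTable":
        df = pd.read_csv(path, comment="#", dtype={"type": str})
        return cls(dict(zip(df["type"], df["Z_k"].astype(float))))


def estimate_discharge_frequency(
    records: Sequence[BallastRecord],
    all_records: Sequence[BallastRecord] | None = None,
) -> DischargeFrequencyTable:
    """Estimate Z_k = (# records of type k with discharge > 0) / (# of type k).

    The frequency must be computed on the record set that still contains the
    zero-discharge reports (validity filtering removes them); pass that set
    as ``all_records``, or as ``records`` if no separate valid subset is
    carried. Types with no records are absent from the table. A pooled
    all-types estimate is stored under the ``__pooled__`` key for fallback
    use on voyage types unseen in the ballast data.
    """
    src = all_records if all_records is not None else records
    totals: dict[str, int] = {}
    nonzero: dict[str, int] = {}
    pooled_total = pooled_nonzero = 0
    for r in src:
        if r.vessel_type is None or r.discharge is None:
            continue
        totals[r.vessel_type] = totals.get(r.vessel_type, 0) + 1
        pooled_total += 1
        if r.discharge > 0:
            nonzero[r.vessel_type] = nonzero.get(r.vessel_type, 0) + 1
            pooled_nonzero += 1
    Z = {k: nonzero.get(k, 0) / n for k, n in totals.items()}
    if pooled_total:
        Z[POOLED] = pooled_nonzero / pooled_total
    return DischargeFrequencyTable(Z)


@dataclass
class DischargeRegression:
    """Fitted predictor of non-zero discharge volume from (type, gwt).

    The default backend is a random-forest ensemble; any object exposing the
    same ``predict(types, gwts) -> array`` contract can stand in. Predictions
    are clipped at zero from below; ``test_r2`` is the coefficient of
    determination on the held-out split.
    """

    model: object
    type_codes: dict[str, int]
    train_fraction: float
    test_r2: float
    pooled_mean_by_type: dict[str, float] = field(default_factory=dict)

    def predict(self, vessel_type: str, gwt: float) -> float:
        if vessel_type not in self.type_codes:
            raise KeyError(f"vessel type {vessel_type!r} not seen at fit time")
        X = np.array([[self.type_codes[vessel_type], gwt]], dtype=float)
        return float(max(0.0, self.model.predict(X)[0]))

    def predict_pooled(self, gwt: float) -> float:
        """Type-agnostic prediction: mean over the fitted types."""
        X = np.array([[code, gwt] for code in self.type_codes.values()], dtype=float)
        return float(max(0.0, np.mean(self.model.predict(X))))


def fit_discharge_regression(
    records: Sequence[BallastRecord],
    train_fraction: float = 0.70,
    seed: int = 0,
    model: object | None = None,
) -> DischargeRegression:
    """Fit the conditional discharge-volume regression W_GWT on valid records.

    ``records`` must already be validity-filtered (non-zero discharges only).
    The data are split into training/testing sets (default 70/30,
    deterministic given ``seed``), the regressor fitted on the training set
    and scored on the held-out set.
    """
    recs = [r for r in records if r.is_valid]
    counts: dict[str, int] = {}
    for r in recs:
        counts[r.vessel_type] = counts.get(r.vessel_type, 0) + 1
    thin = [k for k, n in counts.items() if n < 2]
    if thin or not recs:
        raise ValueError(
            "too few ballast records to fit a regression"
            + (f" for type(s): {', '.join(sorted(thin))}" if thin else "")
        )
    type_codes = {k: i for i, k in enumerate(sorted(counts))}
    X = np.array([[type_codes[r.vessel_type], r.gwt] for r in recs], dtype=float)
    y = np.array([r.discharge for r in recs], dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed,
        stratify=X[:, 0] if min(counts.values()) >= 4 else None,
    )
    if model is None:
        model = RandomForestRegressor(n_estimators=200, random_state=seed, n_jobs=1)
    model.fit(X_tr, y_tr)
    r2 = float(r2_score(y_te, np.asarray(model.predict(X_te))))
    means = {k: float(np.mean(y[X[:, 0] == code]))
             for k, code in type_codes.items()}
    return DischargeRegression(model=model, type_codes=type_codes,
                               train_fraction=train_fraction, test_r2=r2,
                               pooled_mean_by_type=means)


@dataclass
class TypeMap:
    """Total map from raw (source-taxonomy) ship-type labels to the
    9-category vessel taxonomy."""

    mapping: dict[str, str]

    def __getitem__(self, raw: str) -> str:
        try:
            return self.mapping[raw]
        except KeyError:
            raise KeyError(f"unmapped raw ship type: {raw!r}") from None

    def __contains__(self, raw: str) -> bool:
        return raw in self.mapping

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(sorted(self.mapping.items()),
                     columns=["raw_type", "vessel_type"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TypeMap":
        df = pd.read_csv(path, comment="#", dtype=str)
        for col in ("raw_type", "vessel_type"):
            if col not in df.columns:
                raise ValueError(f"type map file missing required column(s): {col}")
        return cls(dict(zip(df["raw_type"], df["vessel_type"])))


def estimate_trip_discharge(
    m: ShipMovement,
    typemap: TypeMap | Mapping[str, str],
    Z: DischargeFrequencyTable,
    reg: DischargeRegression,
) -> float:
    """Expected discharge D = Z_k * W_GWT for one voyage, in metric tons.

    Voyage types absent from the ballast data fall back to the pooled
    (all-types) frequency and a type-averaged volume prediction, with a
    logged warning.
    """
    if isinstance(typemap, Mapping) and not isinstance(typemap, TypeMap):
        typemap = TypeMap(dict(typemap))
    k = typemap[m.ship_type_raw]
    if k in Z and k in reg.type_codes:
        return Z[k] * reg.predict(k, m.gwt)
    if POOLED not in Z:
        raise KeyError(f"vessel type {k!r} absent from discharge data and no "
                       "pooled fallback available")
    logger.warning("vessel type %r absent from ballast data; using pooled "
                   "discharge estimate", k)
    warnings.warn(f"vessel type {k!r} absent from ballast data; using pooled "
                  "estimate", stacklevel=2)
    return Z[POOLED] * reg.predict_pooled(m.gwt)
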