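"""Yearly network metrics, linear trend fitting/projection, and
preferential-attachment rewiring of pathway topology.

Trends are ordinary least squares of metric value on year — a deliberately
simple functional form, since there is no strong basis for any particular
alternative — with 95% bands computed both as confidence intervals on the
mean line and as prediction intervals for new observations. Projections are
flagged as extrapolations, not predictions.

The rewiring simulation emulates the observed concentration of shipping onto
hub ports: pick a random pathway, keep its strength, and re-attach its
target to a port chosen with probability proportional to its current number
of incoming pathways (recomputed after every accepted rewire, the
rich-get-richer mechanism), until the number of distinct recipient ports
falls to a target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .risk import Pathway, Trip, aggregate_pathway_risk

__all__ = [
    "METRIC_NAMES",
    "MetricSeries",
    "TrendFit",
    "RewireConfig",
    "compute_yearly_metrics",
    "fit_trend",
    "project_series",
    "preferential_rewire",
]

METRIC_NAMES: tuple[str, ...] = (
    "n_voyages", "total_dwt", "dwt_per_voyage", "n_pathways",
    "n_recipient_ports", "mean_pathway_risk", "hub_in_pathways",
)


@dataclass
class MetricSeries:
    """A yearly time series of one network metric."""

    metric_name: str
    points: dict[int, float]

    @property
    def years(self) -> list[int]:
        return sorted(self.points)

    @property
    def values(self) -> list[float]:
        return [self.points[y] for y in self.years]


def compute_yearly_metrics(
    trips_by_year: Mapping[int, Sequence[Trip]],
    pathways_by_year: Mapping[int, Sequence[Pathway]],
) -> list[MetricSeries]:
    """Per-year shipping-intensity and pathway-topology metrics.

    Voyage count; total dead weight tonnage (a crude propagule-pressure
    proxy); mean ship capacity (DWT per voyage); distinct pathway count;
    distinct recipient (target) port count; mean pathway risk; and the
    in-pathway count of the best-connected recipient (the hub).
    """
    years = sorted(set(trips_by_year) | set(pathways_by_year))
    if not years:
        raise ValueError("at least one year of data is required")
    series = {name: MetricSeries(name, {}) for name in METRIC_NAMES}
    for y in years:
        trips = list(trips_by_year.get(y, ()))
        pathways = list(pathways_by_year.get(y, ()))
        if not trips and not pathways:
            warnings.warn(f"year {y} has no data; metrics set to 0", stacklevel=2)
        n_voy = len(trips)
        total_dwt = float(sum(t.movement.dwt for t in trips))
        series["n_voyages"].points[y] = float(n_voy)
        series["total_dwt"].points[y] = total_dwt
        series["dwt_per_voyage"].points[y] = total_dwt / n_voy if n_voy else 0.0
        series["n_pathways"].points[y] = float(len(pathways))
        recipients: dict[str, int] = {}
        for p in pathways:
            recipients[p.target] = recipients.get(p.target, 0) + 1
        series["n_recipient_ports"].points[y] = float(len(recipients))
        series["mean_pathway_risk"].points[y] = (
            float(np.mean([p.risk for p in pathways])) if pathways else 0.0)
        series["hub_in_pathways"].points[y] = (
            float(max(recipients.values())) if recipients else 0.0)
    return [series[name] for name in METRIC_NAMES]


@dataclass
class TrendFit:
    """OLS linear trend of a metric on year, with uncertainty.

    Carries the fitted statsmodels results; ``summary()`` delegates to it.
    """

    metric_name: str
    slope: float
    intercept: float
    p_value: float
    slope_stderr: float
    years: list[int]
    values: list[float]
    _results: object = field(repr=False, default=None)

    def summary(self):
        return self._results.summary()

    def predict_mean(self, years: Sequence[int]) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(years, dtype=float)


def fit_trend(series: MetricSeries) -> TrendFit:
    """Ordinary least squares of metric value on year.

    Needs >= 2 points for a line and >= 3 for a meaningful two-sided slope
    p-value (with exactly 2 the p-value is undefined and returned as NaN).
    """
    years = series.years
    if len(years) < 2:
        raise ValueError(
            f"trend fitting needs >= 2 points, got {len(years)} for "
            f"{series.metric_name}")
    X = sm.add_constant(np.asarray(years, dtype=float))
    y = np.asarray(series.values, dtype=float)
    res = sm.OLS(y, X).fit()
    p = float(res.pvalues[1]) if len(years) >= 3 else float("nan")
    return TrendFit(
        metric_name=series.metric_name,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_value=p,
        slope_stderr=float(res.bse[1]),
        years=list(years),
        values=list(y),
        _results=res,
    )


def project_series(fit: TrendFit, horizon_years: int,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Extrapolate the fitted line ``horizon_years`` beyond the last year.

    Returns a frame with columns year, projection, ci_low/ci_high (95%
    confidence band on the mean line) and pi_low/pi_high (95% prediction
    interval for a new observation — the wider band that accompanies
    extrapolated values in plots). ``df.attrs["is_prediction"]`` is False:
    these are trend extrapolations, not forecasts. Horizon 0 → empty frame.
    """
    cols = ["year", "projection", "ci_low", "ci_high", "pi_low", "pi_high"]
    if horizon_years == 0:
        out = pd.DataFrame(columns=cols)
        out.attrs["is_prediction"] = False
        return out
    years = np.arange(fit.years[-1] + 1, fit.years[-1] + 1 + horizon_years)
    X = sm.add_constant(years.astype(float), has_constant="add")
    pred = fit._results.get_prediction(X)
    frame = pred.summary_frame(alpha=alpha)
    out = pd.DataFrame(
        {
            "year": years,
            "projection": frame["mean"].to_numpy(),
            "ci_low": frame["mean_ci_lower"].to_numpy(),
            "ci_high": frame["mean_ci_upper"].to_numpy(),
            "pi_low": frame["obs_ci_lower"].to_numpy(),
            "pi_high": frame["obs_ci_upper"].to_numpy(),
        }
    )
    out.attrs["is_prediction"] = False
    out.attrs["band_plotted"] = "prediction_interval"
    return out


@dataclass(frozen=True)
class RewireConfig:
    """Rewiring run parameters: the number of distinct recipient ports to
    reach, the seed, a cap on rejected draws, and the policy when a rewire
    would duplicate an existing (source, target) pathway ("forbid" rejects
    the draw, preserving the pathway count and strength multiset exactly;
    "merge" probability-unions the strengths)."""

    target_recipient_count: int
    seed: int = 0
    max_attempts: int = 100_000
    duplicate_policy: str = "forbid"

    def __post_init__(self) -> None:
        if self.target_recipient_count < 1:
            raise ValueError("target_recipient_count must be >= 1")
        if self.duplicate_policy not in ("forbid", "merge"):
            raise ValueError(f"unknown duplicate_policy {self.duplicate_policy!r}")


def preferential_rewire(
    pathways: Sequence[Pathway], cfg: RewireConfig
) -> list[Pathway]:
    """Rewire pathway targets preferentially toward well-connected ports
    until the distinct recipient count equals the target.

    Each accepted step picks a pathway uniformly, keeps its strength, and
    re-attaches it to a port drawn with probability proportional to its
    current incoming-pathway count (ports with zero incoming pathways have
    zero attachment weight, and the new target can never equal the pathway's
    own source). The recipient count is non-increasing and drops by at most
    one per step, so the target is met exactly. Deterministic given the seed.
    """
    current = [replace(p, trips=list(p.trips)) for p in pathways]
    recipients = {p.target for p in current}
    if cfg.target_recipient_count > len(recipients):
        raise ValueError(
            f"target_recipient_count {cfg.target_recipient_count} exceeds the "
            f"current recipient count {len(recipients)}")
    if cfg.duplicate_policy == "forbid":
        out_deg: dict[str, int] = {}
        for p in current:
            out_deg[p.source] = out_deg.get(p.source, 0) + 1
        feasible_min = max(out_deg.values(), default=0)
        if cfg.target_recipient_count < feasible_min:
            raise ValueError(
                f"target_recipient_count {cfg.target_recipient_count} is "
                f"unreachable under the 'forbid' duplicate policy: a source "
                f"holds {feasible_min} pathways needing distinct targets")
    rng = np.random.default_rng(cfg.seed)
    attempts = 0
    while len({p.target for p in current}) > cfg.target_recipient_count:
        if attempts >= cfg.max_attempts:
            raise RuntimeError(
                f"rewiring target not reached within {attempts} attempts")
        attempts += 1
        i = int(rng.integers(len(current)))
        p = current[i]
        indeg: dict[str, int] = {}
        for q in current:
            indeg[q.target] = indeg.get(q.target, 0) + 1
        candidates = sorted(t for t in indeg if t != p.source)
        weights = np.array([indeg[t] for t in candidates], dtype=float)
        if weights.sum() == 0:
            raise RuntimeError("no eligible rewiring target with incoming pathways")
        new_target = candidates[int(rng.choice(len(candidates),
                                               p=weights / weights.sum()))]
        if new_target == p.target:
            continue
        clash = next((j for j, q in enumerate(current)
                      if j != i and q.source == p.source
                      and q.target == new_target), None)
        if clash is not None:
            if cfg.duplicate_policy == "forbid":
                continue
            merged = current[clash]
            merged.risk = aggregate_pathway_risk([merged.risk, p.risk])
            merged.n_trips += p.n_trips
            merged.trips = list(merged.trips) + list(p.trips)
            current.pop(i)
        else:
            current[i] = replace(p, target=new_target)
    return current
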