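"""Forecast orchestration: run both methods off predicted weather fields.

For a focal day at lead 1-5 days, Method A classifies the predicted
sea-level-pressure snapshot of the focal day to its SOM node and reports the
node's empirical sighting probability; Method B backtracks an air parcel
24 h through the predicted winds, reads off Lat24, and pushes it with the
ordinal date and a fixed 60-minute observation duration through the fitted
logistic model. The two probabilities are reported side by side, never
averaged. A missing input produces an explicit per-method "missing" entry
with a reason — never a silent zero.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from . import occurrence as occ_mod
from . import seaice as seaice_mod
from . import sompattern as som_mod
from . import trajectory as traj_mod
from .errors import CoverageError, DomainError, FormatError, TimeRangeError
from .metfields import GridField, WindPair

logger = logging.getLogger("gullcast.forecast")

DEFAULT_LEADS = (1, 2, 3, 4, 5)
#: hour (UTC) of the focal-day pressure snapshot fed to Method A, and of the
#: trajectory arrival for Method B
DEFAULT_SNAPSHOT_HOUR = 0


def date_ordinal(d: date) -> int:
    """Day index within the winter season, November 1 = 1.

    Counts continuously through the new year (Dec 1 -> 31, Feb 10 -> 102);
    dates in January-June refer to the season that began the previous
    November.
    """
    anchor_year = d.year if d.month >= 7 else d.year - 1
    return (d - date(anchor_year, 11, 1)).days + 1


def build_covariates(
    records,
    winds: WindPair,
    ice: GridField | None = None,
    ice_mask=None,
    arrival: tuple[float, float] = traj_mod.DEFAULT_ARRIVAL,
    arrival_hour: int = DEFAULT_SNAPSHOT_HOUR,
    hours: float = 72.0,
) -> pd.DataFrame:
    """Assemble the Method B covariate table for fitted analyses.

    One row per sighting record: ordinal date, trajectory covariates from a
    backward trajectory arriving at ``arrival_hour`` UTC of the record's
    date, sea-ice extents when an ice field is supplied, duration and the
    presence response.
    """
    rows = []
    for r in records:
        t_arr = np.datetime64(f"{r.date.isoformat()}T{arrival_hour:02d}:00")
        traj = traj_mod.backtrack(
            winds, arrival[0], arrival[1], arrival_time=t_arr, hours=hours
        )
        feats = traj_mod.features(traj) if hours >= 72 else None
        row = {
            "date": r.date,
            "site": r.site,
            "date_ordinal": date_ordinal(r.date),
            "duration_min": r.duration_min,
            "presence": r.presence,
        }
        if feats is not None:
            row.update(feats.as_dict())
        else:
            lat24, lon24 = traj.position_at(24.0)
            brg, _ = traj_mod.bearing_from_arrival(arrival, (lat24, lon24))
            row.update(lat24=lat24, deg24=brg, left_domain=traj.left_domain)
        if ice is not None:
            ext = seaice_mod.compute_extent(
                ice.slice_at(np.datetime64(r.date.isoformat())), mask=ice_mask
            )
            row.update(
                ice_whole=ext.extent_whole,
                ice_north=ext.extent_north,
                ice_south=ext.extent_south,
            )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MethodAResult:
    probability: float | None
    node_id: int | None
    bmu_distance: float | None
    missing_reason: str | None = None


@dataclass
class MethodBResult:
    probability: float | None
    lat24: float | None
    left_domain: bool | None
    missing_reason: str | None = None


@dataclass
class ForecastReport:
    """Joint 1-5-day-lead report for one focal date."""

    focal_date: date
    entries: dict[int, dict] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        def _m(x):
            return {k: v for k, v in x.__dict__.items()}

        return {
            "focal_date": self.focal_date.isoformat(),
            "leads": {
                str(lead): {
                    "method_a": _m(e["method_a"]),
                    "method_b": _m(e["method_b"]),
                }
                for lead, e in sorted(self.entries.items())
            },
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2)

    def to_csv(self, path) -> None:
        """Table-style layout: one row per method, leads as columns from the
        longest lead (-5 day) to the shortest (-1 day)."""
        leads = sorted(self.entries, reverse=True)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["focal_date", "method"] + [f"-{l} day" for l in leads])
            for name, key in (("Method A", "method_a"), ("Method B", "method_b")):
                row = [self.focal_date.isoformat(), name]
                for l in leads:
                    p = self.entries[l][key].probability
                    row.append("" if p is None else f"{100.0 * p:.1f}")
                w.writerow(row)


def forecast_day(
    focal_date: date,
    nwp_slp: GridField | None,
    nwp_winds: WindPair | None,
    som: som_mod.SomModel,
    table: som_mod.NodeProbabilityTable,
    occ: occ_mod.OccurrenceModel,
    arrival: tuple[float, float] = traj_mod.DEFAULT_ARRIVAL,
    snapshot_hour: int = DEFAULT_SNAPSHOT_HOUR,
    duration_min: float = occ_mod.DEFAULT_FORECAST_DURATION_MIN,
) -> dict:
    """Run both methods for one focal day off predicted fields.

    Method A uses the predicted SLP snapshot at ``snapshot_hour`` UTC of the
    focal day; Method B backtracks 24 h from the arrival point at the same
    instant through the predicted winds (sub-daily winds are linearly
    interpolated to the hourly trajectory steps by the field interpolator).
    """
    t_focal = np.datetime64(f"{focal_date.isoformat()}T{snapshot_hour:02d}:00")

    if nwp_slp is None:
        a = MethodAResult(None, None, None, "no predicted SLP for the focal day")
        logger.warning("method A missing for %s: no SLP field", focal_date)
    else:
        try:
            snap = nwp_slp.slice_at(t_focal)
            prob, node, dist = som_mod.forecast_method_a(som, table, snap)
            reason = "node has no observation days" if prob is None else None
            a = MethodAResult(prob, node, dist, reason)
        except (TimeRangeError, FormatError) as exc:
            a = MethodAResult(None, None, None, str(exc))
            logger.warning("method A missing for %s: %s", focal_date, exc)

    if nwp_winds is None:
        b = MethodBResult(None, None, None, "no predicted winds for the focal day")
        logger.warning("method B missing for %s: no wind fields", focal_date)
    else:
        try:
            traj = traj_mod.backtrack(
                nwp_winds, arrival[0], arrival[1], arrival_time=t_focal, hours=24.0
            )
            lat24, _ = traj.position_at(24.0)
            prob = occ_mod.predict(
                occ,
                lat24=lat24,
                date_ordinal=date_ordinal(focal_date),
                duration_min=duration_min,
            )
            b = MethodBResult(prob, lat24, traj.left_domain)
        except (CoverageError, DomainError, TimeRangeError, FormatError) as exc:
            b = MethodBResult(None, None, None, str(exc))
            logger.warning("method B missing for %s: %s", focal_date, exc)

    return {"method_a": a, "method_b": b}


def forecast_range(
    init_date: date,
    nwp_slp: GridField | None,
    nwp_winds: WindPair | None,
    som: som_mod.SomModel,
    table: som_mod.NodeProbabilityTable,
    occ: occ_mod.OccurrenceModel,
    leads=DEFAULT_LEADS,
    provenance: dict | None = None,
    **kwargs,
) -> ForecastReport:
    """Apply :func:`forecast_day` at each lead from the initialization date.

    Each lead's focal day is ``init_date + lead``; partial archive coverage
    degrades to per-method missing entries rather than failing the report.
    """
    report = ForecastReport(
        focal_date=init_date, provenance=provenance or {}
    )
    for lead in sorted(leads):
        focal = init_date + timedelta(days=int(lead))
        report.entries[int(lead)] = forecast_day(
            focal, nwp_slp, nwp_winds, som, table, occ, **kwargs
        )
    return report
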