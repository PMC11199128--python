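"""Backward air-parcel trajectories and the lagged covariates they yield.

A parcel is assumed to arrive at a fixed coastal point (default 45°N,
145°E, sea level) and is traced backward through the gridded wind field at
hourly steps out to 72 h, with the wind linearly interpolated in space and
time and no vertical motion. The parcel latitude 24/48/72 h before arrival
(Lat24/Lat48/Lat72) and the bearing of the lagged position as seen from the
arrival point (Deg24/Deg48/Deg72, degrees clockwise from north) are the
covariates of the occurrence model: a large Lat24 means air — and, under the
vagrancy hypothesis, birds — reached the site from far north within a day,
i.e. strong northerly flow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import CoverageError, DomainError, TimeRangeError
from .metfields import WindPair, interp_space_time

#: mean Earth radius, km
EARTH_RADIUS_KM = 6371.0
#: meters per degree of latitude (R * pi / 180)
M_PER_DEG = EARTH_RADIUS_KM * 1000.0 * np.pi / 180.0

DEFAULT_ARRIVAL = (45.0, 145.0)


@dataclass
class TrajectoryResult:
    """Backward trajectory from an arrival point.

    ``positions`` holds (lat, lon) per hourly lag, index 0 = arrival.
    When the parcel exits the wind grid the position is frozen at the last
    in-domain location and ``left_domain``/``exit_lag`` record the event.
    """

    arrival_lat: float
    arrival_lon: float
    arrival_time: np.datetime64
    lags_h: np.ndarray          # 0, 1, ..., hours
    positions: np.ndarray       # (n_lags, 2) -> lat, lon
    left_domain: bool
    exit_lag: float | None      # first lag (h) at which the parcel exited

    def position_at(self, lag_h: float) -> tuple[float, float]:
        idx = int(np.argmin(np.abs(self.lags_h - lag_h)))
        if abs(self.lags_h[idx] - lag_h) > 1e-9:
            raise ValueError(f"lag {lag_h} h not on the trajectory's step grid")
        return float(self.positions[idx, 0]), float(self.positions[idx, 1])


def backtrack(
    winds: WindPair,
    arrival_lat: float = DEFAULT_ARRIVAL[0],
    arrival_lon: float = DEFAULT_ARRIVAL[1],
    arrival_time=None,
    hours: float = 72.0,
    step_h: float = 1.0,
) -> TrajectoryResult:
    """First-order backward Euler integration through the wind field.

    Each step moves the parcel against the local wind:
    ``p(t - dt) = p(t) - V(p(t), t) * dt`` with V interpolated bilinearly in
    space and linearly in time. Meters are converted to degrees with the
    spherical factors ``dlat = d / (R*pi/180)`` and
    ``dlon = d / (R*pi/180 * cos(lat))``. A parcel exiting the grid hull is
    frozen there (``left_domain=True``) rather than erroring, so fast-flow
    days still yield covariates.
    """
    if arrival_time is None:
        raise ValueError("arrival_time is required")
    t_arr = np.datetime64(arrival_time, "ns")
    t_start = t_arr - np.timedelta64(int(round(hours * 3600)), "s")
    u = winds.u
    if t_start < u.times[0] or t_arr > u.times[-1]:
        raise CoverageError(
            f"winds cover [{u.times[0]}, {u.times[-1]}], trajectory needs "
            f"[{t_start}, {t_arr}]"
        )
    lat_ok = u.latitudes[0] <= arrival_lat <= u.latitudes[-1]
    lon = float(np.mod(arrival_lon, 360.0))
    lon_ok = u.longitudes[0] <= lon <= u.longitudes[-1]
    if not (lat_ok and lon_ok):
        raise DomainError("arrival point outside the wind grid")

    n_steps = int(round(hours / step_h))
    lags = np.arange(n_steps + 1) * step_h
    pos = np.empty((n_steps + 1, 2))
    pos[0] = (arrival_lat, lon)
    dt_s = step_h * 3600.0
    left, exit_lag = False, None

    lat_c, lon_c = arrival_lat, lon
    t_c = t_arr
    for k in range(1, n_steps + 1):
        if left:
            pos[k] = (lat_c, lon_c)
            continue
        try:
            uu = interp_space_time(winds.u, lat_c, lon_c, t_c)
            vv = interp_space_time(winds.v, lat_c, lon_c, t_c)
        except (DomainError, TimeRangeError):
            left, exit_lag = True, float(lags[k - 1])
            pos[k] = (lat_c, lon_c)
            continue
        lat_new = lat_c - vv * dt_s / M_PER_DEG
        lon_new = lon_c - uu * dt_s / (M_PER_DEG * np.cos(np.radians(lat_c)))
        lon_new = float(np.mod(lon_new, 360.0))
        t_c = t_c - np.timedelta64(int(round(dt_s * 1e9)), "ns")
        in_dom = (
            u.latitudes[0] <= lat_new <= u.latitudes[-1]
            and u.longitudes[0] <= lon_new <= u.longitudes[-1]
        )
        if not in_dom:
            left, exit_lag = True, float(lags[k])
            # freeze at the last in-domain position
            lat_new, lon_new = lat_c, lon_c
        lat_c, lon_c = lat_new, lon_new
        pos[k] = (lat_c, lon_c)

    return TrajectoryResult(
        arrival_lat=arrival_lat,
        arrival_lon=lon,
        arrival_time=t_arr,
        lags_h=lags,
        positions=pos,
        left_domain=left,
        exit_lag=exit_lag,
    )


def bearing_from_arrival(
    arrival: tuple[float, float], point: tuple[float, float]
) -> tuple[float, float | None]:
    """Bearing of ``point`` as seen from ``arrival``, degrees clockwise from
    north in [0, 360).

    Planar approximation with cos-latitude scaling of the zonal offset:
    ``atan2(dx, dy)`` with ``dx = (lon_p - lon_a) * cos(mean lat)`` and
    ``dy = lat_p - lat_a``. Coincident points return bearing 0.0 with a
    degenerate flag (second element None means well-defined; the flag value
    0.0 marks degeneracy).

    Returns
    -------
    (bearing_deg, degenerate) : bearing in [0, 360); degenerate is True when
    the points coincide.
    """
    lat_a, lon_a = arrival
    lat_p, lon_p = point
    dlon = (np.mod(lon_p, 360.0) - np.mod(lon_a, 360.0) + 180.0) % 360.0 - 180.0
    dy = lat_p - lat_a
    dx = dlon * np.cos(np.radians(0.5 * (lat_a + lat_p)))
    if abs(dx) < 1e-12 and abs(dy) < 1e-12:
        return 0.0, True
    bearing = float(np.degrees(np.arctan2(dx, dy)) % 360.0)
    return bearing, False


@dataclass
class TrajectoryFeatures:
    """Lagged-position covariates of one backward trajectory."""

    lat24: float
    lat48: float
    lat72: float
    deg24: float
    deg48: float
    deg72: float
    left_domain: bool

    def as_dict(self) -> dict:
        return {
            "lat24": self.lat24,
            "lat48": self.lat48,
            "lat72": self.lat72,
            "deg24": self.deg24,
            "deg48": self.deg48,
            "deg72": self.deg72,
            "left_domain": self.left_domain,
        }


def features(traj: TrajectoryResult) -> TrajectoryFeatures:
    """Read off Lat24/48/72 and Deg24/48/72 from a trajectory.

    Bearings are from the arrival point toward the lagged parcel position.
    For a trajectory flagged ``left_domain`` the frozen boundary position
    feeds the features and the flag is carried through for audit.
    """
    arrival = (traj.arrival_lat, traj.arrival_lon)
    out = {}
    for lag in (24, 48, 72):
        if traj.lags_h[-1] + 1e-9 < lag:
            raise CoverageError(f"trajectory shorter than {lag} h")
        lat, lon = traj.position_at(lag)
        brg, _ = bearing_from_arrival(arrival, (lat, lon))
        out[f"lat{lag}"] = lat
        out[f"deg{lag}"] = brg
    return TrajectoryFeatures(left_domain=traj.left_domain, **out)
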