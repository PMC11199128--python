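"""Regular lat-lon gridded meteorological fields.

The data model every other module consumes: a :class:`GridField` is one
variable (sea-level pressure, a 10-m wind component, or sea-ice fraction)
on a regular latitude-longitude grid with a time axis, plus the space-time
interpolation and reductions used by the pattern classifier and the
trajectory integrator.

Conventions
-----------
* latitudes: degrees north, strictly ascending; grid-cell-center registration
* longitudes: degrees east in [0, 360), strictly ascending
* times: UTC, ascending
* values: array indexed (time, lat, lon)
* no extrapolation — queries outside the grid hull or the time range raise,
  so a trajectory leaving the domain is detected rather than silently clamped
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    DomainError,
    EmptyDayError,
    FormatError,
    TimeRangeError,
    UnsupportedGridError,
)

_LAT_NAMES = ("lat", "latitude", "Latitude", "LAT")
_LON_NAMES = ("lon", "longitude", "Longitude", "LON")
_TIME_NAMES = ("time", "Time", "TIME")

#: plausible sea-level-pressure bounds, hPa (record extremes with margin)
SLP_BOUNDS = (870.0, 1090.0)


@dataclass
class GridField:
    """One meteorological variable on a regular lat-lon grid.

    Parameters
    ----------
    variable_name : str
        e.g. ``"slp"``, ``"u10"``, ``"v10"``, ``"ice"``.
    units : str
        ``"hPa"``, ``"m s-1"`` or ``"fraction"``.
    latitudes, longitudes : ndarray
        Strictly ascending cell-center coordinates (degrees N / degrees E).
    times : ndarray of datetime64[ns]
        Ascending UTC timestamps.
    values : ndarray, shape (ntime, nlat, nlon)
    """

    variable_name: str
    units: str
    latitudes: np.ndarray
    longitudes: np.ndarray
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.latitudes = np.asarray(self.latitudes, dtype=float)
        self.longitudes = np.asarray(self.longitudes, dtype=float)
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None, :, :]
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not np.all(np.diff(self.latitudes) > 0):
            raise FormatError("latitudes must be strictly ascending")
        if not np.all(np.diff(self.longitudes) > 0):
            raise FormatError("longitudes must be strictly ascending")
        expected = (len(self.times), len(self.latitudes), len(self.longitudes))
        if self.values.shape != expected:
            raise FormatError(
                f"values shape {self.values.shape} inconsistent with axes {expected}"
            )
        if self.variable_name.lower() in ("slp", "msl", "prmsl"):
            finite = np.isfinite(self.values)
            if not finite.all():
                raise FormatError("SLP values must be finite")
            lo, hi = SLP_BOUNDS
            if self.values.min() < lo or self.values.max() > hi:
                raise FormatError(
                    f"SLP outside plausible range [{lo}, {hi}] hPa: "
                    f"[{self.values.min():.1f}, {self.values.max():.1f}]"
                )
        if self.units == "fraction":
            v = self.values[np.isfinite(self.values)]
            if v.size and (v.min() < -1e-9 or v.max() > 1 + 1e-9):
                raise FormatError("ice fraction outside [0, 1]")

    # -- conveniences -----------------------------------------------------
    @property
    def nlat(self) -> int:
        return len(self.latitudes)

    @property
    def nlon(self) -> int:
        return len(self.longitudes)

    def slice_at(self, t) -> "GridField":
        """Single-time slice at an exact snapshot time."""
        t = np.datetime64(t, "ns")
        idx = np.nonzero(self.times == t)[0]
        if idx.size == 0:
            raise TimeRangeError(f"no snapshot at {t}")
        return replace(
            self,
            times=self.times[idx[0] : idx[0] + 1],
            values=self.values[idx[0] : idx[0] + 1],
        )

    def same_grid(self, other: "GridField") -> bool:
        return (
            self.latitudes.shape == other.latitudes.shape
            and self.longitudes.shape == other.longitudes.shape
            and np.allclose(self.latitudes, other.latitudes)
            and np.allclose(self.longitudes, other.longitudes)
        )

    def to_xarray(self) -> xr.DataArray:
        return xr.DataArray(
            self.values,
            coords={"time": self.times, "lat": self.latitudes, "lon": self.longitudes},
            dims=("time", "lat", "lon"),
            name=self.variable_name,
            attrs={"units": self.units},
        )


@dataclass
class WindPair:
    """Eastward (u) and northward (v) 10-m wind components on one grid."""

    u: GridField
    v: GridField

    def __post_init__(self) -> None:
        if not (
            self.u.same_grid(self.v)
            and len(self.u.times) == len(self.v.times)
            and np.array_equal(self.u.times, self.v.times)
        ):
            raise FormatError("u and v must share identical axes")


# ---------------------------------------------------------------------------
# NetCDF I/O
# ---------------------------------------------------------------------------

def _find_coord(ds: xr.Dataset, names) -> str:
    for n in names:
        if n in ds.coords or n in ds.dims:
            return n
    raise FormatError(
        f"no coordinate among {names}; found {list(ds.coords)}"
    )


def read_grid(path, variable: str) -> GridField:
    """Read one variable from a CF-style NetCDF file.

    Latitude rows are reordered ascending if stored descending; longitudes
    are normalized to [0, 360). Raises :class:`FormatError` naming the
    available variables if ``variable`` is absent, and
    :class:`UnsupportedGridError` for non-regular grids.
    """
    with xr.open_dataset(path, engine="scipy") as ds:
        if variable not in ds.data_vars:
            raise FormatError(
                f"variable {variable!r} not in file; available: "
                f"{sorted(ds.data_vars)}"
            )
        da = ds[variable]
        lat_name = _find_coord(ds, _LAT_NAMES)
        lon_name = _find_coord(ds, _LON_NAMES)
        time_name = _find_coord(ds, _TIME_NAMES)
        lats = np.asarray(da[lat_name], dtype=float)
        lons = np.asarray(da[lon_name], dtype=float)
        if lats.ndim != 1 or lons.ndim != 1:
            raise UnsupportedGridError("only regular 1-D lat/lon axes supported")
        if lats.size > 2:
            steps = np.diff(np.sort(lats))
            if not np.allclose(steps, steps[0], rtol=1e-3, atol=1e-6):
                raise UnsupportedGridError("latitude spacing is not uniform")
        da = da.transpose(time_name, lat_name, lon_name)
        values = np.asarray(da.values, dtype=float)
        # descending latitude -> flip rows
        if lats.size > 1 and lats[1] < lats[0]:
            lats = lats[::-1].copy()
            values = values[:, ::-1, :].copy()
        # longitude to [0, 360)
        lons = np.mod(lons, 360.0)
        order = np.argsort(lons)
        if not np.array_equal(order, np.arange(lons.size)):
            lons = lons[order]
            values = values[:, :, order]
        units = str(da.attrs.get("units", ""))
        times = np.asarray(da[time_name].values, dtype="datetime64[ns]")
        return GridField(variable, units, lats, lons, times, values)


def write_grid(field: GridField, path) -> None:
    """Write a GridField to NetCDF (classic format, CF-style coordinates)."""
    field.to_xarray().to_dataset().to_netcdf(path, engine="scipy")


# ---------------------------------------------------------------------------
# interpolation and reductions
# ---------------------------------------------------------------------------

def _bracket(axis: np.ndarray, x: float, kind: str):
    """Indices (i0, i1) and weight w of x on an ascending axis; exact
    endpoints allowed, no extrapolation."""
    if x < axis[0] or x > axis[-1]:
        exc = TimeRangeError if kind == "time" else DomainError
        raise exc(f"{kind} {x} outside [{axis[0]}, {axis[-1]}]")
    i1 = int(np.searchsorted(axis, x, side="left"))
    if i1 == 0:
        return 0, 0, 0.0
    if axis[i1 - 1] == x:
        return i1 - 1, i1 - 1, 0.0
    i0 = i1 - 1
    w = (x - axis[i0]) / (axis[i1] - axis[i0])
    return i0, i1, float(w)


def interp_space_time(field: GridField, lat: float, lon: float, t) -> float:
    """Bilinear in space, linear in time; exact on grid nodes at snapshots.

    Raises :class:`DomainError` for points outside the grid hull and
    :class:`TimeRangeError` for instants outside the field's coverage —
    never extrapolates.
    """
    lon = float(np.mod(lon, 360.0))
    t64 = np.datetime64(t, "ns")
    taxis = field.times.astype("int64").astype(float)
    k0, k1, wt = _bracket(taxis, float(t64.astype("int64")), "time")
    i0, i1, wy = _bracket(field.latitudes, float(lat), "latitude")
    j0, j1, wx = _bracket(field.longitudes, lon, "longitude")

    def plane(k: int) -> float:
        v = field.values[k]
        return (
            v[i0, j0] * (1 - wy) * (1 - wx)
            + v[i0, j1] * (1 - wy) * wx
            + v[i1, j0] * wy * (1 - wx)
            + v[i1, j1] * wy * wx
        )

    if k0 == k1:
        return float(plane(k0))
    return float(plane(k0) * (1 - wt) + plane(k1) * wt)


def daily_mean(field: GridField, day) -> GridField:
    """Arithmetic mean of all snapshots within one UTC calendar day.

    This is the convention used to realize a "daily" pressure pattern from
    sub-daily analysis snapshots; the output carries the day (00 UTC) as its
    timestamp. Raises :class:`EmptyDayError` when the day holds no snapshot.
    """
    if isinstance(day, str):
        day = date.fromisoformat(day)
    d0 = np.datetime64(pd.Timestamp(day).normalize(), "ns")
    d1 = d0 + np.timedelta64(1, "D")
    sel = (field.times >= d0) & (field.times < d1)
    if not sel.any():
        raise EmptyDayError(f"no snapshots on {day}")
    mean = field.values[sel].mean(axis=0)
    return replace(field, times=np.array([d0]), values=mean[None])


def subset_region(
    field: GridField,
    lat_min: float,
    lat_max: float,
    lon_min: float,
    lon_max: float,
) -> GridField:
    """Cells whose centers lie inside the closed lat/lon box."""
    lon_min, lon_max = np.mod(lon_min, 360.0), np.mod(lon_max, 360.0)
    lat_sel = (field.latitudes >= lat_min) & (field.latitudes <= lat_max)
    if lon_min <= lon_max:
        lon_sel = (field.longitudes >= lon_min) & (field.longitudes <= lon_max)
    else:  # box crossing the 0 meridian
        lon_sel = (field.longitudes >= lon_min) | (field.longitudes <= lon_max)
    if not lat_sel.any() or not lon_sel.any():
        raise DomainError("subset box does not intersect the grid")
    return replace(
        field,
        latitudes=field.latitudes[lat_sel],
        longitudes=field.longitudes[lon_sel],
        values=field.values[:, lat_sel][:, :, lon_sel],
    )


def flatten_pattern(field: GridField) -> np.ndarray:
    """Row-major (lat varies slowest) vector of a single time slice."""
    if len(field.times) != 1:
        raise FormatError("flatten_pattern needs a single time slice")
    return field.values[0].reshape(-1).copy()


def unflatten_pattern(vector: np.ndarray, template: GridField) -> np.ndarray:
    """Inverse of :func:`flatten_pattern` on the template's grid shape."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != template.nlat * template.nlon:
        raise FormatError(
            f"vector length {vector.size} != {template.nlat * template.nlon}"
        )
    return vector.reshape(template.nlat, template.nlon)
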