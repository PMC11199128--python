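"""Shared fixtures: small analytic wind fields and one large synthetic season.

The large season is session-scoped because several statistical checks
(parameter recovery, model-selection study, node-probability/wind coupling)
share the same simulated weather and differ only in the sighting draw.
"""

from __future__ import annotations

import numpy as np
import pytest

from gullcast import GridField, WindPair, gen_season


def make_uniform_winds(
    u_val: float,
    v_val: float,
    lat_range=(20.0, 70.0),
    lon_range=(110.0, 180.0),
    step: float = 1.25,
    t0="2019-11-29T00:00",
    n_times: int = 29,
    dt_h: int = 6,
) -> WindPair:
    """Spatially/temporally constant wind on a wide grid (wide enough that a
    24-72 h trajectory at ~10 m/s stays inside)."""
    lats = np.arange(lat_range[0], lat_range[1] + 1e-9, step)
    lons = np.arange(lon_range[0], lon_range[1] + 1e-9, step)
    times = np.datetime64(t0) + np.arange(n_times) * np.timedelta64(dt_h, "h")
    shape = (n_times, len(lats), len(lons))
    mk = lambda name, val: GridField(
        name, "m s-1", lats, lons, times, np.full(shape, float(val))
    )
    return WindPair(u=mk("u10", u_val), v=mk("v10", v_val))


def make_field(values, lats, lons, times, name="slp", units="hPa") -> GridField:
    return GridField(name, units, np.asarray(lats, float), np.asarray(lons, float),
                     np.asarray(times, dtype="datetime64[ns]"), np.asarray(values, float))


@pytest.fixture(scope="session")
def big_season():
    """~2000-day synthetic record: (slp, winds, ice)."""
    return gen_season(2002, seed=101)


@pytest.fixture(scope="session")
def small_season():
    """A two-month synthetic winter for orchestration tests."""
    return gen_season(62, seed=7)
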