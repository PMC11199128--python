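"""Sea-ice extent covariates over the Sea of Okhotsk.

"Extent" here defaults to the area-weighted mean ice fraction over a mask
(weights proportional to cos latitude, i.e. cell area on a regular lat-lon
grid), reported for the whole masked region and for its halves north and
south of a split latitude (51°N by default, roughly the middle of the sea).
A thresholded convention (fraction of area with concentration >= 15%) is
available via ``method="threshold"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np

from .errors import DomainError
from .metfields import GridField

#: rectangular proxy for the Sea of Okhotsk (degrees N / E)
DEFAULT_MASK_BOX = (44.0, 62.0, 135.0, 157.0)
DEFAULT_SPLIT_LAT = 51.0
THRESHOLD_CONCENTRATION = 0.15


@dataclass
class IceExtent:
    """Mean ice fraction over the mask and its north/south halves."""

    date: date | None
    extent_whole: float
    extent_north: float
    extent_south: float

    def __post_init__(self) -> None:
        vals = [v for v in (self.extent_north, self.extent_south) if np.isfinite(v)]
        if vals and np.isfinite(self.extent_whole):
            assert min(vals) - 1e-9 <= self.extent_whole <= max(vals) + 1e-9


def box_mask(field: GridField, box=DEFAULT_MASK_BOX) -> np.ndarray:
    """Boolean (lat, lon) mask of cell centers inside a closed box,
    intersected with the field's ocean cells (finite, non-NaN values)."""
    lat_min, lat_max, lon_min, lon_max = box
    la = (field.latitudes >= lat_min) & (field.latitudes <= lat_max)
    lo = (field.longitudes >= lon_min) & (field.longitudes <= lon_max)
    mask = np.outer(la, lo)
    ocean = np.isfinite(field.values).all(axis=0)
    return mask & ocean


def compute_extent(
    ice: GridField,
    mask: np.ndarray | None = None,
    split_lat: float = DEFAULT_SPLIT_LAT,
    method: str = "mean",
) -> IceExtent:
    """Area-weighted ice extent of a single-day ice-fraction slice.

    ``method="mean"`` averages the fraction itself; ``method="threshold"``
    averages the indicator fraction >= 15%. Cells whose center lies exactly
    on ``split_lat`` count as north. Raises :class:`DomainError` when the
    mask selects no cell.
    """
    if len(ice.times) != 1:
        raise DomainError("compute_extent expects a single time slice")
    if mask is None:
        mask = box_mask(ice)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (ice.nlat, ice.nlon):
        raise DomainError("mask shape does not match the ice grid")
    if not mask.any():
        raise DomainError("empty mask region")

    vals = ice.values[0]
    if method == "threshold":
        vals = (vals >= THRESHOLD_CONCENTRATION).astype(float)
    elif method != "mean":
        raise ValueError(f"unknown method {method!r}")

    w = np.cos(np.radians(ice.latitudes))[:, None] * np.ones(ice.nlon)[None, :]
    north = mask & (ice.latitudes[:, None] >= split_lat)
    south = mask & (ice.latitudes[:, None] < split_lat)

    def wmean(sel):
        if not sel.any():
            return float("nan")
        return float(np.average(vals[sel], weights=w[sel]))

    day = ice.times[0].astype("datetime64[D]").astype(object)
    return IceExtent(
        date=day,
        extent_whole=wmean(mask),
        extent_north=wmean(north),
        extent_south=wmean(south),
    )
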