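"""Monitoring records and the filters that define the analysis datasets.

Sighting surveys of a vagrant gull produce one record per site-day: a date,
an observation duration, and a bird count. Because a wandering individual
can linger for several days, runs of nearby presence days are collapsed to
the single day that best marks the arrival event, and absence days adjacent
to sightings (the bird may still have been around) are dropped. A separate
effort filter removes days watched too briefly to trust a non-detection.

De-duplication rules
--------------------
Presence days at one site are chained into a period whenever successive
presence days are at most ``gap_days`` (default 2) calendar days apart
(same day is impossible per site; next day or a one-day gap chain). Within
each period only the earliest day attaining the period's maximum count is
kept. Absence days within ``absence_window`` (default 2, two-sided) days of
ANY original presence day at the same site are removed; remaining absence
days chained at <= ``gap_days`` spacing keep only the first of each chain.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date, timedelta

from .errors import FormatError

DEFAULT_MONTHS = frozenset({11, 12, 1, 2})
DEFAULT_GAP_DAYS = 2
DEFAULT_ABSENCE_WINDOW = 2
DEFAULT_MIN_MINUTES = 45.0


@dataclass(frozen=True)
class SightingRecord:
    """One observation occasion: a site-day with effort and outcome."""

    date: date
    site: str
    duration_min: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise FormatError(f"negative count on {self.date}")
        if not (self.duration_min >= 0):
            raise FormatError(f"invalid duration on {self.date}")

    @property
    def presence(self) -> bool:
        return self.count > 0


@dataclass
class FilterReport:
    """Accounting of the de-duplication/effort pipeline."""

    n_input: int
    n_presence_kept: int
    n_absence_kept: int
    n_removed_presence: int
    n_removed_absence: int
    kept: list = field(default_factory=list)

    def __post_init__(self) -> None:
        assert self.n_presence_kept + self.n_absence_kept == len(self.kept)
        assert min(
            self.n_input,
            self.n_presence_kept,
            self.n_absence_kept,
            self.n_removed_presence,
            self.n_removed_absence,
        ) >= 0

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_presence_kept": self.n_presence_kept,
            "n_absence_kept": self.n_absence_kept,
            "n_removed_presence": self.n_removed_presence,
            "n_removed_absence": self.n_removed_absence,
        }


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def window_filter(records, months=DEFAULT_MONTHS):
    """Keep records whose month falls in the analysis window (Nov-Feb by
    default), preserving order."""
    months = frozenset(months)
    return [r for r in records if r.date.month in months]


def _by_site(records):
    sites: dict[str, list[SightingRecord]] = {}
    for r in records:
        sites.setdefault(r.site, []).append(r)
    for s in sites.values():
        s.sort(key=lambda r: r.date)
    return sites


def dedup_presence(records, gap_days: int = DEFAULT_GAP_DAYS):
    """Collapse runs of nearby presence days to their first highest-count day.

    Returns (kept, removed); absence records pass through untouched in
    ``kept``'s complement handling — this operation looks at presence days
    only and the caller recombines.
    """
    kept, removed = [], []
    for _, recs in sorted(_by_site(records).items()):
        pres = [r for r in recs if r.presence]
        periods: list[list[SightingRecord]] = []
        for r in pres:
            if periods and (r.date - periods[-1][-1].date).days <= gap_days:
                periods[-1].append(r)
            else:
                periods.append([r])
        for period in periods:
            best = max(period, key=lambda r: r.count)
            # earliest day attaining the period maximum
            winner = next(r for r in period if r.count == best.count)
            kept.append(winner)
            removed.extend(r for r in period if r is not winner)
    kept.sort(key=lambda r: (r.site, r.date))
    removed.sort(key=lambda r: (r.site, r.date))
    return kept, removed


def dedup_absence(
    records,
    presence_days=None,
    gap_days: int = DEFAULT_GAP_DAYS,
    absence_window: int = DEFAULT_ABSENCE_WINDOW,
):
    """Drop absence days near sightings, then thin clustered absences.

    ``presence_days`` is the per-site set of ALL original presence dates
    (not just de-duplicated ones); if None it is taken from ``records``.
    An absence day within ``absence_window`` days (two-sided) of any such
    date is removed; the survivors are chained at <= ``gap_days`` spacing
    and only the first day of each chain is kept.
    """
    if presence_days is None:
        presence_days = {}
        for r in records:
            if r.presence:
                presence_days.setdefault(r.site, set()).add(r.date)
    kept, removed = [], []
    for site, recs in sorted(_by_site(records).items()):
        pres_dates = presence_days.get(site, set())
        survivors = []
        for r in recs:
            if r.presence:
                continue
            if any(abs((r.date - d).days) <= absence_window for d in pres_dates):
                removed.append(r)
            else:
                survivors.append(r)
        chains: list[list[SightingRecord]] = []
        for r in survivors:
            if chains and (r.date - chains[-1][-1].date).days <= gap_days:
                chains[-1].append(r)
            else:
                chains.append([r])
        for chain in chains:
            kept.append(chain[0])
            removed.extend(chain[1:])
    kept.sort(key=lambda r: (r.site, r.date))
    removed.sort(key=lambda r: (r.site, r.date))
    return kept, removed


def effort_filter(records, min_minutes: float = DEFAULT_MIN_MINUTES):
    """Keep records watched for at least ``min_minutes`` (>= convention: a
    record of exactly the threshold is kept)."""
    return [r for r in records if r.duration_min >= min_minutes]


def apply_filters(
    records,
    months=DEFAULT_MONTHS,
    gap_days: int = DEFAULT_GAP_DAYS,
    absence_window: int = DEFAULT_ABSENCE_WINDOW,
) -> FilterReport:
    """Window filter then presence/absence de-duplication; effort filtering
    is a separate, method-specific step (see :func:`effort_filter`)."""
    windowed = window_filter(records, months)
    pres_kept, pres_removed = dedup_presence(windowed, gap_days)
    abs_kept, abs_removed = dedup_absence(
        windowed, gap_days=gap_days, absence_window=absence_window
    )
    kept = sorted(pres_kept + abs_kept, key=lambda r: (r.site, r.date))
    return FilterReport(
        n_input=len(records),
        n_presence_kept=len(pres_kept),
        n_absence_kept=len(abs_kept),
        n_removed_presence=len(pres_removed),
        n_removed_absence=len(abs_removed),
        kept=kept,
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("date", "site", "duration_min", "count")


def read_sightings(path) -> list[SightingRecord]:
    """Read records from CSV with columns date (ISO-8601), site,
    duration_min, count. Malformed rows raise :class:`FormatError` with the
    offending line number."""
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not set(_COLUMNS) <= set(reader.fieldnames):
            raise FormatError(
                f"CSV must have columns {_COLUMNS}, found {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                d = date.fromisoformat(row["date"].strip())
                count = int(row["count"])
                dur = float(row["duration_min"])
                out.append(SightingRecord(d, row["site"].strip(), dur, count))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"line {lineno}: {exc}") from exc
    return out


def write_sightings(records, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow([r.date.isoformat(), r.site, r.duration_min, r.count])
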