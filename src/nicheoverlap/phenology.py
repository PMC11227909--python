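"""Breeding-time niche arithmetic.

All breeding-season dates are expressed as season days ("Julian days" in the
field convention): integer day indices with 1 April = 1, counted within one
calendar year. Breeding periods run from the earliest first-egg date to the
latest hatching date of a species and are inclusive of both endpoints, so an
8 April–1 July period is 85 days long. The breeding-time overlap of a focal
species is the fraction of its own breeding period that is shared with the
other species, expressed as a percentage.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SEASON_START",
    "BreedingRecord",
    "BreedingPeriod",
    "to_julian",
    "from_julian",
    "breeding_period",
    "period_overlap_fraction",
    "hatching_rate",
    "read_breeding_csv",
    "write_breeding_csv",
    "phenology_summary",
]

#: First day of the analysis window (month, day): 1 April maps to day 1.
SEASON_START = (4, 1)
#: Last admissible calendar day (month, day) of the window: 31 July.
SEASON_END = (7, 31)


def to_julian(date: dt.date) -> int:
    """Convert a calendar date to a season day index (1 April = 1).

    Parameters
    ----------
    date
        Calendar date between 1 April and 31 July of its year.

    Returns
    -------
    int
        Day index: 1 April -> 1, 2 April -> 2, ..., 1 May -> 31.

    Raises
    ------
    ValueError
        If the date falls outside the 1 April – 31 July window.
    """
    start = dt.date(date.year, *SEASON_START)
    end = dt.date(date.year, *SEASON_END)
    if not (start <= date <= end):
        raise ValueError(
            f"date {date.isoformat()} outside the breeding-season window "
            f"({start.isoformat()} to {end.isoformat()})"
        )
    return (date - start).days + 1


def from_julian(day: int, year: int) -> dt.date:
    """Inverse of :func:`to_julian`: season day index -> calendar date."""
    start = dt.date(year, *SEASON_START)
    date = start + dt.timedelta(days=int(day) - 1)
    if date > dt.date(year, *SEASON_END):
        raise ValueError(f"day {day} falls after the season window end")
    if day < 1:
        raise ValueError(f"day {day} before season start")
    return date


@dataclass
class BreedingRecord:
    """One nest's phenology dates and clutch/brood counts.

    ``first_egg <= incubation_start <= hatching`` and
    ``0 <= brood_size <= clutch_size`` are enforced at construction.
    """

    nest_id: str
    species: str
    year: int
    first_egg: dt.date
    incubation_start: dt.date
    hatching: dt.date
    clutch_size: int
    brood_size: int | None = None

    def __post_init__(self) -> None:
        if not (self.first_egg <= self.incubation_start <= self.hatching):
            raise ValueError(
                f"nest {self.nest_id}: dates must satisfy "
                "first_egg <= incubation_start <= hatching"
            )
        if self.clutch_size < 0:
            raise ValueError(f"nest {self.nest_id}: clutch_size must be >= 0")
        if self.brood_size is not None and not (0 <= self.brood_size <= self.clutch_size):
            raise ValueError(
                f"nest {self.nest_id}: brood_size must be in [0, clutch_size]"
            )


@dataclass(frozen=True)
class BreedingPeriod:
    """A species' breeding period in season days, inclusive of endpoints."""

    species: str
    start_julian: int
    end_julian: int

    def __post_init__(self) -> None:
        if self.end_julian < self.start_julian:
            raise ValueError("end_julian must be >= start_julian")

    @property
    def length_days(self) -> int:
        return self.end_julian - self.start_julian + 1


def breeding_period(
    records: Iterable[BreedingRecord],
    species: str,
    year: int | None = None,
) -> BreedingPeriod:
    """Breeding period of one species: earliest first egg to latest hatching.

    Years are pooled by default; pass ``year`` to restrict to a single season.
    """
    recs = [r for r in records if r.species == species]
    if year is not None:
        recs = [r for r in recs if r.year == year]
    if not recs:
        raise ValueError(f"no breeding records for species {species!r}")
    start = min(to_julian(r.first_egg) for r in recs)
    end = max(to_julian(r.hatching) for r in recs)
    return BreedingPeriod(species=species, start_julian=start, end_julian=end)


def period_overlap_fraction(focal: BreedingPeriod, other: BreedingPeriod) -> float:
    """Percentage of the focal species' breeding period shared with the other.

    The co-breeding span is the inclusive intersection of the two periods
    (0 days when disjoint); the result is ``100 * shared / focal.length_days``,
    in [0, 100]. Not symmetric: a short period nested inside a long one
    overlaps 100% from the short species' view.
    """
    lo = max(focal.start_julian, other.start_julian)
    hi = min(focal.end_julian, other.end_julian)
    shared = max(0, hi - lo + 1)
    return 100.0 * shared / focal.length_days


def hatching_rate(record: BreedingRecord) -> float:
    """Hatching rate of one nest: brood size / clutch size, in [0, 1]."""
    if record.clutch_size == 0:
        raise ValueError(f"nest {record.nest_id}: clutch_size is zero")
    if record.brood_size is None:
        raise ValueError(f"nest {record.nest_id}: brood_size not recorded")
    return record.brood_size / record.clutch_size


# ---------------------------------------------------------------------------
# I/O and summaries

_CSV_COLUMNS = [
    "nest_id",
    "species",
    "year",
    "first_egg",
    "incubation_start",
    "hatching",
    "clutch_size",
    "brood_size",
]


def read_breeding_csv(path) -> list[BreedingRecord]:
    """Read breeding records from CSV with ISO dates (see ``_CSV_COLUMNS``)."""
    df = pd.read_csv(path, dtype={"nest_id": str, "species": str})
    records = []
    for row in df.itertuples(index=False):
        brood = getattr(row, "brood_size", None)
        if brood is not None and pd.isna(brood):
            brood = None
        records.append(
            BreedingRecord(
                nest_id=str(row.nest_id),
                species=str(row.species),
                year=int(row.year),
                first_egg=dt.date.fromisoformat(str(row.first_egg)),
                incubation_start=dt.date.fromisoformat(str(row.incubation_start)),
                hatching=dt.date.fromisoformat(str(row.hatching)),
                clutch_size=int(row.clutch_size),
                brood_size=None if brood is None else int(brood),
            )
        )
    return records


def write_breeding_csv(records: Sequence[BreedingRecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "nest_id": r.nest_id,
                "species": r.species,
                "year": r.year,
                "first_egg": r.first_egg.isoformat(),
                "incubation_start": r.incubation_start.isoformat(),
                "hatching": r.hatching.isoformat(),
                "clutch_size": r.clutch_size,
                "brood_size": r.brood_size,
            }
            for r in records
        ],
        columns=_CSV_COLUMNS,
    )
    df.to_csv(path, index=False)


def phenology_summary(records: Sequence[BreedingRecord]) -> dict:
    """Periods, pairwise overlap fractions and hatching rates for all species.

    Returns a JSON-serialisable dict keyed by species, plus an
    ``"overlap_pct"`` entry mapping ``focal->other`` pairs to percentages.
    """
    species = sorted({r.species for r in records})
    periods = {s: breeding_period(records, s) for s in species}
    out: dict = {"species": {}, "overlap_pct": {}}
    for s in species:
        p = periods[s]
        rates = [
            hatching_rate(r)
            for r in records
            if r.species == s and r.brood_size is not None and r.clutch_size > 0
        ]
        entry = {
            "start_julian": p.start_julian,
            "end_julian": p.end_julian,
            "length_days": p.length_days,
        }
        if rates:
            arr = np.asarray(rates, dtype=float)
            entry["hatching_rate_mean"] = float(arr.mean())
            entry["hatching_rate_se"] = (
                float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
            )
            entry["n_hatching"] = int(arr.size)
        out["species"][s] = entry
    for s in species:
        for t in species:
            if s != t:
                out["overlap_pct"][f"{s}->{t}"] = period_overlap_fraction(
                    periods[s], periods[t]
                )
    return out
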