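"""Domain types, fire-perimeter geometry, and BACIPS group assignment.

A BACIPS (Before-After Control-Impact Paired Series) design classifies every
observation of a marked animal by *period* (before vs. after a disturbance)
and *treatment* (impact = inside a disturbance footprint, control = outside).
This module houses the data containers for nest monitoring records, adult
monthly encounter histories and fire events, the spatial overlay that maps a
telemetry location to one of the four BACIPS groups, the decision tree that
resolves conflicting within-month group observations, and the month-by-group
probability-weight matrix (pi) used as the prior for months with no
relocations.

Coordinates are planar meters throughout; no CRS transformation is performed.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.geometry.base import BaseGeometry

__all__ = [
    "BacipsGroup",
    "Location",
    "FireEvent",
    "NestRecord",
    "MonthState",
    "AdultMonthlyHistory",
    "PiMatrix",
    "StudyMonths",
    "point_in_polygon",
    "polygon_area_ha",
    "burned_percent",
    "assign_group",
    "resolve_month_group",
    "build_nest_records",
    "build_adult_histories",
    "estimate_pi",
]


class BacipsGroup(IntEnum):
    """The four BACIPS groups, coded 1-4: BC, BI, AC, AI."""

    BC = 1  # before-control
    BI = 2  # before-impact
    AC = 3  # after-control
    AI = 4  # after-impact

    @property
    def is_impact(self) -> bool:
        return self in (BacipsGroup.BI, BacipsGroup.AI)

    @property
    def is_after(self) -> bool:
        return self in (BacipsGroup.AC, BacipsGroup.AI)

    @classmethod
    def from_flags(cls, impact: bool, after: bool) -> "BacipsGroup":
        if impact:
            return cls.AI if after else cls.BI
        return cls.AC if after else cls.BC


@dataclass(frozen=True)
class Location:
    """A single telemetry relocation in planar meters."""

    bird_id: str
    date: dt.date
    x: float
    y: float
    status: str = "alive"  # alive | dead

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates for bird {self.bird_id}")
        if self.status not in ("alive", "dead"):
            raise ValueError(f"unknown status {self.status!r} for bird {self.bird_id}")


def _validate_perimeter(geom: BaseGeometry) -> BaseGeometry:
    if not isinstance(geom, (Polygon, MultiPolygon)):
        raise ValueError(f"perimeter must be Polygon or MultiPolygon, got {geom.geom_type}")
    polys = geom.geoms if isinstance(geom, MultiPolygon) else [geom]
    for poly in polys:
        if len(set(poly.exterior.coords[:-1])) < 3:
            raise ValueError("degenerate polygon: fewer than 3 distinct vertices")
    if not geom.is_valid:
        raise ValueError("invalid (self-intersecting) perimeter")
    if geom.area <= 0:
        raise ValueError("perimeter has zero area")
    return geom


@dataclass(frozen=True)
class FireEvent:
    """A named wildfire: perimeter polygon(s) plus ignition date."""

    name: str
    start_date: dt.date
    perimeter: BaseGeometry

    def __post_init__(self) -> None:
        _validate_perimeter(self.perimeter)

    def contains(self, x: float, y: float) -> bool:
        """Boundary points count as inside (conservative toward treatment)."""
        return bool(self.perimeter.covers(Point(x, y)))


@dataclass(frozen=True)
class NestRecord:
    """One nest's exposure interval, fate and covariates.

    ``exposure_days`` runs from the date the nest was found to the hatch
    date for successes, and to the last date observed active (floor one day)
    for failures; quick failures between the first and second visit are
    retained with one day of assumed survival.
    """

    nest_id: str
    bird_id: str
    age_class: str  # yearling | adult
    location: Location
    date_found: dt.date
    date_last_active: dt.date
    date_fate: dt.date
    fate: str  # success | failure
    exposure_days: int
    group: BacipsGroup

    def __post_init__(self) -> None:
        if not (self.date_found <= self.date_last_active <= self.date_fate):
            raise ValueError(
                f"nest {self.nest_id}: dates must satisfy found <= last_active <= fate"
            )
        if self.fate not in ("success", "failure"):
            raise ValueError(f"nest {self.nest_id}: unknown fate {self.fate!r}")
        if self.age_class not in ("yearling", "adult"):
            raise ValueError(f"nest {self.nest_id}: unknown age class {self.age_class!r}")
        if self.exposure_days < 1:
            raise ValueError(f"nest {self.nest_id}: exposure_days must be >= 1")


@dataclass(frozen=True)
class MonthState:
    """State of one bird in one study month."""

    state: str  # alive | dead | censored
    group: BacipsGroup | None  # None = no relocation that month (missing)
    age_class: str  # yearling | adult


@dataclass
class AdultMonthlyHistory:
    """Per-bird monthly encounter history from entry month to exit month."""

    bird_id: str
    entry_month: int  # study-month index of first relocation
    months: list[MonthState]

    def __post_init__(self) -> None:
        if not self.months:
            raise ValueError(f"bird {self.bird_id}: empty history")
        states = [m.state for m in self.months]
        if states[0] not in ("alive",):
            raise ValueError(f"bird {self.bird_id}: first state must be alive")
        if "dead" in states and (states.count("dead") > 1 or states[-1] != "dead"):
            raise ValueError(f"bird {self.bird_id}: dead state must be unique and terminal")
        ages = [m.age_class for m in self.months]
        for prev, cur in zip(ages, ages[1:]):
            if prev == "adult" and cur == "yearling":
                raise ValueError(f"bird {self.bird_id}: age class reverted adult->yearling")


@dataclass
class PiMatrix:
    """M x 4 matrix of BACIPS-group probability weights, one row per study month."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != 4:
            raise ValueError("pi matrix must be M x 4")
        if (self.weights < 0).any():
            raise ValueError("pi matrix entries must be non-negative")
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-12):
            raise ValueError("each pi row must sum to 1")

    def row(self, month_index: int) -> np.ndarray:
        return self.weights[month_index]


@dataclass(frozen=True)
class StudyMonths:
    """Calendar-month index over the study window (month 0 = first month)."""

    start_year: int = 2008
    start_month: int = 1
    n_months: int = 144

    def index(self, date: dt.date) -> int:
        idx = (date.year - self.start_year) * 12 + (date.month - self.start_month)
        if not 0 <= idx < self.n_months:
            raise ValueError(f"date {date} outside study window")
        return idx

    def calendar_month(self, index: int) -> int:
        """1..12 calendar month of a study-month index."""
        return (self.start_month - 1 + index) % 12 + 1

    def year_of(self, index: int) -> int:
        return self.start_year + (self.start_month - 1 + index) // 12

    def first_date(self, index: int) -> dt.date:
        return dt.date(self.year_of(index), self.calendar_month(index), 1)


# ---------------------------------------------------------------------------
# geometry


def point_in_polygon(point: tuple[float, float], polygon: BaseGeometry | FireEvent) -> bool:
    """True iff the point is inside or on the boundary of the polygon."""
    geom = polygon.perimeter if isinstance(polygon, FireEvent) else polygon
    _validate_perimeter(geom)
    return bool(geom.covers(Point(point)))


def polygon_area_ha(polygon: BaseGeometry | FireEvent) -> float:
    """Planar area in hectares (outer rings minus holes); coordinates in meters."""
    geom = polygon.perimeter if isinstance(polygon, FireEvent) else polygon
    _validate_perimeter(geom)
    return geom.area / 10_000.0


def burned_percent(burned_ha: float, study_ha: float) -> float:
    """Percent of the study area burned, rounded to one decimal."""
    if study_ha <= 0:
        raise ValueError("study area must be positive")
    if burned_ha < 0:
        raise ValueError("burned area must be non-negative")
    return round(100.0 * burned_ha / study_ha, 1)


# ---------------------------------------------------------------------------
# BACIPS group assignment


def assign_group(location: Location, fires: Sequence[FireEvent]) -> BacipsGroup:
    """Assign the BACIPS group of one relocation.

    Treatment is *impact* iff the point lies inside (or on the boundary of)
    any fire perimeter, at any date — points inside a future burn footprint
    are the before-impact group. Period is *after* iff the location date is
    on or past the start of the earliest fire containing the point (impact),
    or past the earliest fire start overall (control).
    """
    if not fires:
        raise ValueError("fires must be non-empty")
    containing = [f for f in fires if f.contains(location.x, location.y)]
    if containing:
        cutoff = min(f.start_date for f in containing)
        return BacipsGroup.from_flags(impact=True, after=location.date >= cutoff)
    cutoff = min(f.start_date for f in fires)
    return BacipsGroup.from_flags(impact=False, after=location.date >= cutoff)


def resolve_month_group(observed_groups: Iterable[BacipsGroup]) -> BacipsGroup:
    """Resolve multiple within-month group observations to one group.

    Hierarchy of assumed impact: treatment beats period, so if any observed
    group is impact, control observations are discarded; among what remains,
    an after-period group beats a before-period group.
    """
    groups = set(observed_groups)
    if not groups:
        raise ValueError("observed_groups must be non-empty")
    if any(g.is_impact for g in groups):
        groups = {g for g in groups if g.is_impact}
    after = [g for g in groups if g.is_after]
    if after:
        return after[0]
    return next(iter(groups))


# ---------------------------------------------------------------------------
# encounter-history construction

_FATE_ALIASES = {
    "success": "success",
    "successful": "success",
    "hatched": "success",
    "hatch": "success",
    "failure": "failure",
    "failed": "failure",
    "unsuccessful": "failure",
    "depredated": "failure",
    "abandoned": "failure",
}


def normalize_fate(raw: str) -> str:
    try:
        return _FATE_ALIASES[str(raw).strip().lower()]
    except KeyError:
        raise ValueError(f"unknown nest fate label {raw!r}") from None


def _as_date(value) -> dt.date:
    if isinstance(value, dt.datetime):
        return value.date()
    if isinstance(value, dt.date):
        return value
    return dt.date.fromisoformat(str(value).strip())


def build_nest_records(
    raw_nest_rows: pd.DataFrame | Iterable[Mapping],
    fires: Sequence[FireEvent],
) -> list[NestRecord]:
    """Build validated NestRecords from raw monitoring rows.

    Exposure runs from the found date to the fate date for successes and to
    the last-active date for failures, with a one-day floor (nests failing
    between the first and second visit are assumed to survive one day).
    The BACIPS group comes from the nest location and found date.
    """
    if isinstance(raw_nest_rows, pd.DataFrame):
        rows = raw_nest_rows.to_dict("records")
    else:
        rows = list(raw_nest_rows)
    records = []
    for row in rows:
        nest_id = str(row["nest_id"])
        try:
            found = _as_date(row["date_found"])
            last_active = _as_date(row["date_last_active"])
            fate_date = _as_date(row["date_fate"])
            fate = normalize_fate(row["fate"])
            if not (found <= last_active <= fate_date):
                raise ValueError("dates must satisfy found <= last_active <= fate")
            loc = Location(str(row["bird_id"]), found, float(row["x"]), float(row["y"]))
            if fate == "success":
                exposure = (fate_date - found).days
            else:
                exposure = (last_active - found).days
            record = NestRecord(
                nest_id=nest_id,
                bird_id=str(row["bird_id"]),
                age_class=str(row["age_class"]).strip().lower(),
                location=loc,
                date_found=found,
                date_last_active=last_active,
                date_fate=fate_date,
                fate=fate,
                exposure_days=max(exposure, 1),
                group=assign_group(loc, fires),
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"nest row {nest_id!r}: {exc}") from exc
        records.append(record)
    return records


def _graduation_index(capture_date: dt.date, months: StudyMonths) -> int:
    """Study-month index at which a yearling captured on capture_date turns adult.

    Yearlings graduate into the adult age class on the first 1 March strictly
    after capture and stay adult thereafter.
    """
    year = capture_date.year if capture_date < dt.date(capture_date.year, 3, 1) else capture_date.year + 1
    return (year - months.start_year) * 12 + (3 - months.start_month)


def build_adult_histories(
    locations: Iterable[Location],
    fires: Sequence[FireEvent],
    study_months: StudyMonths,
    capture_ages: Mapping[str, str] | None = None,
) -> list[AdultMonthlyHistory]:
    """Build monthly encounter histories from telemetry relocations.

    One state per study month from the month first located through the month
    the bird left the study (death, detected by a ``dead`` relocation, or
    censoring at last contact). Months with relocations in more than one
    group are resolved with the decision-tree hierarchy; months with no
    relocation are flagged missing. Birds captured as yearlings graduate to
    the adult age class on 1 March.
    """
    capture_ages = capture_ages or {}
    by_bird: dict[str, list[Location]] = {}
    for loc in locations:
        by_bird.setdefault(loc.bird_id, []).append(loc)

    histories = []
    for bird_id in sorted(by_bird):
        locs = sorted(by_bird[bird_id], key=lambda l: l.date)
        death_dates = [l.date for l in locs if l.status == "dead"]
        if death_dates:
            death_date = min(death_dates)
            if any(l.date > death_date for l in locs):
                raise ValueError(f"bird {bird_id}: relocations after recorded death")
        entry = study_months.index(locs[0].date)
        exit_month = study_months.index(locs[-1].date)

        month_groups: dict[int, list[BacipsGroup]] = {}
        for loc in locs:
            month_groups.setdefault(study_months.index(loc.date), []).append(
                assign_group(loc, fires)
            )

        age0 = str(capture_ages.get(bird_id, "adult")).strip().lower()
        if age0 not in ("yearling", "adult"):
            raise ValueError(f"bird {bird_id}: unknown capture age class {age0!r}")
        grad = _graduation_index(locs[0].date, study_months) if age0 == "yearling" else entry

        death_month = study_months.index(death_dates[0]) if death_dates else None
        if death_month is not None and death_month == entry:
            # death in the capture month: no alive anchor, so the bird cannot
            # enter the risk set (standard known-fate handling-effect rule)
            continue
        states = []
        for m in range(entry, exit_month + 1):
            groups = month_groups.get(m)
            group = resolve_month_group(groups) if groups else None
            state = "dead" if (death_month is not None and m == death_month) else "alive"
            age = "adult" if m >= grad else "yearling"
            states.append(MonthState(state=state, group=group, age_class=age))
        histories.append(AdultMonthlyHistory(bird_id=bird_id, entry_month=entry, months=states))
    return histories


def estimate_pi(
    histories: Sequence[AdultMonthlyHistory], study_months: StudyMonths
) -> PiMatrix:
    """Estimate the month-by-group probability-weight matrix pi.

    Row m holds the observed group proportions among non-missing bird-months
    in study month m. Months with no observations borrow the pooled
    proportions of the same calendar month across years (sage-grouse are
    social and spatially aggregated in winter, when sparsity occurs), and
    fall back to the overall pooled proportions.
    """
    counts = np.zeros((study_months.n_months, 4))
    for hist in histories:
        for offset, ms in enumerate(hist.months):
            if ms.group is not None:
                counts[hist.entry_month + offset, ms.group - 1] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no observed groups in any month")

    overall = counts.sum(axis=0) / total
    by_cal = np.zeros((12, 4))
    for m in range(study_months.n_months):
        by_cal[study_months.calendar_month(m) - 1] += counts[m]

    weights = np.empty_like(counts)
    for m in range(study_months.n_months):
        row = counts[m]
        if row.sum() > 0:
            weights[m] = row / row.sum()
        else:
            cal = by_cal[study_months.calendar_month(m) - 1]
            weights[m] = cal / cal.sum() if cal.sum() > 0 else overall
    return PiMatrix(weights)
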