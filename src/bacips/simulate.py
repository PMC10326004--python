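"""Synthetic telemetry study generator with stored ground truth.

Emulates a 12-year (2008-2019) VHF telemetry study of radio-marked female
sage-grouse exposed to two mid-study wildfires, with the statistical
structure the BACIPS survival analysis assumes:

* a rectangular study area of ~123,600 ha containing two overlapping fire
  perimeters (~22,300 ha and ~32,600 ha in-study) with start dates
  2016-07-28 and 2017-07-11;
* 178 birds captured in spring and fall cohorts spread across years, a
  share of them yearlings that graduate to adults on 1 March;
* site-fidelic movement — a reflected AR(1) Gaussian walk around a fixed
  home center, a share of home centers lying inside the future burn
  footprints (philopatry keeps birds there after the fires);
* monthly survival driven by the adult hazard model's own closed form
  (group x calendar-month x age x per-bird frailty), with the four group
  annual survivals set to the study-condition values (0.79, 0.71, 0.77,
  0.42) by default;
* nests initiated in spring, daily fates drawn from the nest hazard model
  (37-day window; default group survivals 0.16, 0.19, 0.19, 0.05), found
  within a few days and then checked every 3 days;
* an observation process with seasonal relocation probabilities (sparse in
  winter, dense April-July), collar-loss censoring, and mortality-sensor
  death detection.

Ground truth (true group survivals, BACIPS ratios, frailties, and the true
BACIPS group of every bird-month) is returned alongside the data for
parameter-recovery testing. Identical seeds give identical output.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely import affinity
from shapely.geometry import Polygon, box, mapping
from shapely.ops import unary_union

from .grouping import (
    BacipsGroup,
    FireEvent,
    Location,
    StudyMonths,
    assign_group,
)

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "SimulatedDataset",
    "simulate_scenario",
    "default_study_config",
]

NEST_T = 37


def _default_study_area() -> Polygon:
    # 38,000 m x 32,528.08 m = 123,607 ha
    return box(0.0, 0.0, 38_000.0, 1.23607e9 / 38_000.0)


def _scaled_blob(coords, target_m2: float, cx: float, cy: float) -> Polygon:
    poly = Polygon(coords)
    f = float(np.sqrt(target_m2 / poly.area))
    poly = affinity.scale(poly, xfact=f, yfact=f, origin="centroid")
    c = poly.centroid
    return affinity.translate(poly, xoff=cx - c.x, yoff=cy - c.y)


def _default_fires() -> list[FireEvent]:
    """Two irregular (concave) perimeters scaled to the in-study burned areas."""
    vmfc_coords = [
        (0, 0), (4, -1), (7, 1), (8, 4), (6, 6), (7, 9), (4, 10),
        (1, 8), (2, 5), (-1, 4), (-1, 1),
    ]
    lvf_coords = [
        (0, 0), (5, -2), (9, -1), (12, 2), (10, 5), (11, 8), (7, 10),
        (3, 9), (4, 6), (0, 5), (-2, 2),
    ]
    vmfc = _scaled_blob(vmfc_coords, 22_282e4, 12_500.0, 21_000.0)
    lvf = _scaled_blob(lvf_coords, 32_585e4, 25_000.0, 11_500.0)
    return [
        FireEvent("VMFC", dt.date(2016, 7, 28), vmfc),
        FireEvent("LVF", dt.date(2017, 7, 11), lvf),
    ]


# calendar-month relocation probabilities (Jan..Dec): sparse in winter,
# dense April-July when most monitoring effort occurs
_RELOC_P = (0.5, 0.5, 0.8, 0.95, 0.95, 0.95, 0.95, 0.8, 0.8, 0.8, 0.5, 0.5)
_EXTRA_RELOC_P = (0.1, 0.1, 0.15, 0.4, 0.4, 0.4, 0.4, 0.15, 0.1, 0.1, 0.1, 0.1)


@dataclass
class SimConfig:
    """Study-condition settings of the synthetic scenario."""

    n_birds: int = 178
    study_months: StudyMonths = field(default_factory=StudyMonths)
    fires: list[FireEvent] = field(default_factory=_default_fires)
    study_area: Polygon = field(default_factory=_default_study_area)
    # per-group (BC, BI, AC, AI) true survivals
    true_adult_annual_survival: tuple = (0.79, 0.71, 0.77, 0.42)
    true_nest_survival_37d: tuple = (0.16, 0.19, 0.19, 0.05)
    month_fx_amplitude: float = 0.25
    adult_frailty_sd: float = 0.25
    nest_frailty_sd: float = 0.25
    beta_yearling_adult: float = 0.2
    beta_yearling_nest: float = 0.2
    prop_yearling_at_capture: float = 0.35
    home_inside_prob: float = 0.58
    movement_sd: float = 1200.0
    movement_ar: float = 0.6
    # once their home range burns, birds shift to intact sagebrush outside
    # the footprint for the non-breeding season (Sep-Feb; burned areas lose
    # both winter diet and escape cover), returning for nesting
    winter_shift_outside: bool = True
    reloc_jitter_sd: float = 120.0
    monthly_reloc_prob: tuple = _RELOC_P
    extra_reloc_prob: tuple = _EXTRA_RELOC_P
    monthly_censor_prob: float = 0.015
    nest_init_prob: float = 0.30
    renest_prob: float = 0.4
    # capture effort multiplier for years from the first fire on (field crews
    # replace post-fire mortalities to maintain the marked sample)
    postfire_capture_boost: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.prop_yearling_at_capture,
            self.home_inside_prob,
            self.monthly_censor_prob,
            self.nest_init_prob,
            self.renest_prob,
            *self.monthly_reloc_prob,
            *self.extra_reloc_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for s in (*self.true_adult_annual_survival, *self.true_nest_survival_37d):
            if not 0.0 < s <= 1.0:
                raise ValueError("true survivals must lie in (0, 1]")

    # ---- truth on the model's own scale -----------------------------------

    def true_month_fx(self) -> np.ndarray:
        """Calendar-month log-hazard offsets (sum to zero, peak hazard in May)."""
        m = np.arange(1, 13)
        return self.month_fx_amplitude * np.cos(2 * np.pi * (m - 5) / 12.0)

    def true_adult_eta(self) -> np.ndarray:
        """Group log-hazards solving exp(-sum_m exp(eta+fx_m)) = annual survival."""
        fx_sum = np.exp(self.true_month_fx()).sum()
        s = np.asarray(self.true_adult_annual_survival)
        with np.errstate(divide="ignore"):
            return np.where(s >= 1.0, -np.inf, np.log(-np.log(np.maximum(s, 1e-300)) / fx_sum))

    def true_nest_alpha(self) -> np.ndarray:
        """Group daily log-hazards solving exp(-37 exp(alpha)) = 37-d survival."""
        s = np.asarray(self.true_nest_survival_37d)
        with np.errstate(divide="ignore"):
            return np.where(s >= 1.0, -np.inf, np.log(-np.log(np.maximum(s, 1e-300)) / NEST_T))

    def config_hash(self) -> str:
        payload = {
            k: (v.wkt if isinstance(v, Polygon) else v)
            for k, v in self.__dict__.items()
            if k not in ("fires", "study_months")
        }
        payload["fires"] = [(f.name, f.start_date.isoformat(), f.perimeter.wkt) for f in self.fires]
        sm = self.study_months
        payload["study_months"] = (sm.start_year, sm.start_month, sm.n_months)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass
class SimulationTruth:
    """Ground truth of a simulated scenario, on the analysis scale."""

    adult_annual_survival: dict
    nest_survival_37d: dict
    bacips_ratio_adult: float
    bacips_ratio_nest: float
    adult_frailty: dict
    nest_frailty: dict
    true_groups: pd.DataFrame  # bird_id, study_month, group (1-4)

    def to_json_dict(self) -> dict:
        return {
            "adult_annual_survival": {g.name: v for g, v in self.adult_annual_survival.items()},
            "nest_survival_37d": {g.name: v for g, v in self.nest_survival_37d.items()},
            "bacips_ratio_adult": self.bacips_ratio_adult,
            "bacips_ratio_nest": self.bacips_ratio_nest,
            "adult_frailty": self.adult_frailty,
            "nest_frailty": self.nest_frailty,
            "true_groups": self.true_groups.to_dict("list"),
        }


@dataclass
class SimulatedDataset:
    telemetry: pd.DataFrame  # bird_id, date, x, y, status
    nests: pd.DataFrame
    birds: pd.DataFrame  # bird_id, capture_date, age_at_capture
    fires_geojson: dict
    truth: SimulationTruth


def default_study_config(seed: int = 0) -> SimConfig:
    """The default study-condition scenario (178 birds, two fires, truths set
    to the study's group survival point values)."""
    return SimConfig(seed=seed)


def _plugin_bacips(s: Sequence[float]) -> float:
    bc, bi, ac, ai = s
    return (ai / ac) / (bi / bc)


def _sample_homes(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    union = unary_union([f.perimeter for f in config.fires])
    shapely.prepare(union)
    minx, miny, maxx, maxy = config.study_area.bounds
    uminx, uminy, umaxx, umaxy = union.bounds
    homes = np.empty((config.n_birds, 2))
    inside = rng.random(config.n_birds) < config.home_inside_prob
    for i in range(config.n_birds):
        if inside[i]:
            while True:
                x = rng.uniform(uminx, umaxx)
                y = rng.uniform(uminy, umaxy)
                if shapely.contains_xy(union, x, y):
                    break
        else:
            while True:
                x = rng.uniform(minx, maxx)
                y = rng.uniform(miny, maxy)
                if not shapely.contains_xy(union, x, y):
                    break
        homes[i] = (x, y)
    if not inside.any():
        raise ValueError(
            "no birds with home centers inside future fire perimeters: "
            "scenario cannot exercise the impact groups"
        )

    # winter centers: nearest intact shrubland outside the burn footprint
    winter = homes.copy()
    if config.winter_shift_outside:
        c = np.array([union.centroid.x, union.centroid.y])
        for i in range(config.n_birds):
            if not shapely.contains_xy(union, homes[i, 0], homes[i, 1]):
                continue
            d = homes[i] - c
            norm = np.hypot(*d)
            d = d / norm if norm > 0 else np.array([1.0, 0.0])
            t = 0.0
            p = homes[i]
            while shapely.contains_xy(union, p[0], p[1]) and t < 1e6:
                t += 500.0
                p = homes[i] + d * t
            p = p + d * 2000.0
            winter[i, 0] = _reflect(p[0], minx, maxx)
            winter[i, 1] = _reflect(p[1], miny, maxy)
    return homes, winter


def _reflect(v: float, lo: float, hi: float) -> float:
    if v < lo:
        v = lo + (lo - v)
    if v > hi:
        v = hi - (v - hi)
    return min(max(v, lo), hi)


def simulate_scenario(config: SimConfig) -> SimulatedDataset:
    """Generate one synthetic dataset plus ground truth.

    Returns telemetry rows, nest monitoring rows, a capture table, the fire
    perimeters as a GeoJSON FeatureCollection dict, and a SimulationTruth.
    """
    rng = np.random.default_rng(config.seed)
    sm = config.study_months
    for f in config.fires:
        shapely.prepare(f.perimeter)
    homes, winter_homes = _sample_homes(config, rng)
    minx, miny, maxx, maxy = config.study_area.bounds

    eta_true = config.true_adult_eta()
    fx_true = config.true_month_fx()
    alpha_nest = config.true_nest_alpha()
    gamma_adult = rng.normal(0.0, config.adult_frailty_sd, config.n_birds)
    gamma_nest = rng.normal(0.0, config.nest_frailty_sd, config.n_birds)

    n_digits = len(str(config.n_birds))
    bird_ids = [f"B{i + 1:0{n_digits}d}" for i in range(config.n_birds)]

    # capture cohorts: spring or fall seasons every study year, with boosted
    # effort from the first fire year on
    capture_month_idx = np.empty(config.n_birds, int)
    capture_day = rng.integers(1, 28, config.n_birds)
    n_years = sm.n_months // 12
    first_fire_year = min(f.start_date.year for f in config.fires)
    year_w = np.array(
        [
            config.postfire_capture_boost
            if sm.start_year + y >= first_fire_year
            else 1.0
            for y in range(n_years)
        ]
    )
    year_w /= year_w.sum()
    for i in range(config.n_birds):
        year = int(rng.choice(n_years, p=year_w))
        month = int(rng.choice([3, 4]) if rng.random() < 0.5 else rng.choice([9, 10, 11]))
        capture_month_idx[i] = year * 12 + (month - sm.start_month)
    yearling_at_capture = rng.random(config.n_birds) < config.prop_yearling_at_capture

    telemetry_rows = []
    truth_rows = []
    nest_rows = []
    bird_rows = []
    nest_counter = 0

    for i, bird in enumerate(bird_ids):
        entry = int(capture_month_idx[i])
        cap_date = dt.date(sm.year_of(entry), sm.calendar_month(entry), int(capture_day[i]))
        age_cap = "yearling" if yearling_at_capture[i] else "adult"
        bird_rows.append((bird, cap_date.isoformat(), age_cap))
        grad_year = cap_date.year if cap_date < dt.date(cap_date.year, 3, 1) else cap_date.year + 1
        grad_idx = (grad_year - sm.start_year) * 12 + (3 - sm.start_month)

        pos = homes[i].copy()
        # the winter shift starts only once the bird's home range has burned
        burn_starts = [
            sm.index(f.start_date)
            for f in config.fires
            if f.contains(homes[i][0], homes[i][1])
        ]
        home_burn_month = min(burn_starts) if burn_starts else None
        alive_month_pos: dict[int, np.ndarray] = {}
        alive_age: dict[int, str] = {}
        died_month = None
        for m in range(entry, sm.n_months):
            cal0 = sm.calendar_month(m)
            shifted = (
                cal0 in (9, 10, 11, 12, 1, 2)
                and home_burn_month is not None
                and m >= home_burn_month
            )
            center = winter_homes[i] if shifted else homes[i]
            pos = center + config.movement_ar * (pos - center) + rng.normal(
                0.0, config.movement_sd, 2
            )
            pos[0] = _reflect(pos[0], minx, maxx)
            pos[1] = _reflect(pos[1], miny, maxy)
            year, cal = sm.year_of(m), sm.calendar_month(m)
            yearling = (m < grad_idx) if yearling_at_capture[i] else False

            # relocations this month
            relocs = []  # (day, x, y)
            if m == entry:
                jit = rng.normal(0.0, config.reloc_jitter_sd, 2)
                relocs.append((int(capture_day[i]), pos[0] + jit[0], pos[1] + jit[1]))
            if rng.random() < config.monthly_reloc_prob[cal - 1]:
                day = int(rng.integers(2, 28))
                jit = rng.normal(0.0, config.reloc_jitter_sd, 2)
                relocs.append((day, pos[0] + jit[0], pos[1] + jit[1]))
            if rng.random() < config.extra_reloc_prob[cal - 1]:
                day = int(rng.integers(2, 28))
                jit = rng.normal(0.0, config.reloc_jitter_sd, 2)
                relocs.append((day, pos[0] + jit[0], pos[1] + jit[1]))
            relocs.sort(key=lambda r: r[0])

            # the bird's true group this month: where it actually was when
            # first relocated, else its (unobserved) mid-month position
            if relocs:
                d0, x0, y0 = relocs[0]
                true_loc = Location(bird, dt.date(year, cal, d0), x0, y0)
            else:
                true_loc = Location(bird, dt.date(year, cal, 15), pos[0], pos[1])
            group = assign_group(true_loc, config.fires)
            truth_rows.append((bird, m, int(group)))

            uh = np.exp(
                eta_true[group - 1]
                + fx_true[cal - 1]
                + (config.beta_yearling_adult if yearling else 0.0)
                + gamma_adult[i]
            )
            alive_month_pos[m] = pos.copy()
            alive_age[m] = "yearling" if yearling else "adult"
            dies = rng.random() < -np.expm1(-uh)
            for day, x, y in relocs:
                telemetry_rows.append(
                    (bird, dt.date(year, cal, day).isoformat(), x, y, "alive")
                )
            if dies:
                # mortality sensor: carcass recovered at the bird's location
                telemetry_rows.append(
                    (bird, dt.date(year, cal, 28).isoformat(), pos[0], pos[1], "dead")
                )
                died_month = m
                break
            if rng.random() < config.monthly_censor_prob:
                break  # collar lost: censored at last contact

        # nesting: one initiation decision per spring the bird was monitored
        for year in range(sm.start_year, sm.start_year + sm.n_months // 12):
            april = (year - sm.start_year) * 12 + (4 - sm.start_month)
            if april not in alive_month_pos:
                continue
            if rng.random() >= config.nest_init_prob:
                continue
            attempt_date = dt.date(year, 3, 25) + dt.timedelta(days=int(rng.integers(0, 50)))
            for attempt in range(2):
                nest_xy = alive_month_pos[april] + rng.normal(0.0, 400.0, 2)
                nest_loc = Location(bird, attempt_date, nest_xy[0], nest_xy[1])
                ngroup = assign_group(nest_loc, config.fires)
                h = np.exp(
                    alpha_nest[ngroup - 1]
                    + (config.beta_yearling_nest if alive_age[april] == "yearling" else 0.0)
                    + gamma_nest[i]
                )
                p_day = -np.expm1(-h)
                fail_day = None
                for d in range(1, NEST_T + 1):
                    if rng.random() < p_day:
                        fail_day = d
                        break
                found_delay = int(rng.integers(0, 4))
                if fail_day is not None and fail_day <= found_delay:
                    break  # failed before ever being found; nest unobserved
                found = attempt_date + dt.timedelta(days=found_delay)
                nest_counter += 1
                nid = f"N{nest_counter:04d}"
                if fail_day is None:
                    last_check = found_delay + 3 * ((NEST_T - found_delay) // 3)
                    nest_rows.append(
                        (
                            nid, bird, alive_age[april], nest_xy[0], nest_xy[1],
                            found.isoformat(),
                            (attempt_date + dt.timedelta(days=last_check)).isoformat(),
                            (attempt_date + dt.timedelta(days=NEST_T)).isoformat(),
                            "success",
                        )
                    )
                    break
                la = found_delay + 3 * ((fail_day - 1 - found_delay) // 3)
                fate_day = la + 3
                fate_date = attempt_date + dt.timedelta(days=fate_day)
                nest_rows.append(
                    (
                        nid, bird, alive_age[april], nest_xy[0], nest_xy[1],
                        found.isoformat(),
                        (attempt_date + dt.timedelta(days=la)).isoformat(),
                        fate_date.isoformat(),
                        "failure",
                    )
                )
                if fate_date > dt.date(year, 6, 15) or rng.random() >= config.renest_prob:
                    break
                attempt_date = fate_date + dt.timedelta(days=7 + int(rng.integers(0, 8)))

    telemetry = pd.DataFrame(
        telemetry_rows, columns=["bird_id", "date", "x", "y", "status"]
    ).sort_values(["bird_id", "date"], kind="stable", ignore_index=True)
    nests = pd.DataFrame(
        nest_rows,
        columns=[
            "nest_id", "bird_id", "age_class", "x", "y",
            "date_found", "date_last_active", "date_fate", "fate",
        ],
    )
    birds = pd.DataFrame(bird_rows, columns=["bird_id", "capture_date", "age_at_capture"])

    fires_geojson = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.perimeter),
                "properties": {"name": f.name, "start_date": f.start_date.isoformat()},
            }
            for f in config.fires
        ],
    }

    groups = list(BacipsGroup)
    truth = SimulationTruth(
        adult_annual_survival={g: float(config.true_adult_annual_survival[g - 1]) for g in groups},
        nest_survival_37d={g: float(config.true_nest_survival_37d[g - 1]) for g in groups},
        bacips_ratio_adult=_plugin_bacips(config.true_adult_annual_survival),
        bacips_ratio_nest=_plugin_bacips(config.true_nest_survival_37d),
        adult_frailty={b: float(g) for b, g in zip(bird_ids, gamma_adult)},
        nest_frailty={b: float(g) for b, g in zip(bird_ids, gamma_nest)},
        true_groups=pd.DataFrame(truth_rows, columns=["bird_id", "study_month", "group"]),
    )
    return SimulatedDataset(
        telemetry=telemetry, nests=nests, birds=birds,
        fires_geojson=fires_geojson, truth=truth,
    )
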