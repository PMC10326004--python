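import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon, box

from bacips import (
    AdultMonthlyHistory,
    BacipsGroup,
    FireEvent,
    Location,
    MonthState,
    PiMatrix,
    assign_group,
    build_adult_histories,
    build_nest_records,
    burned_percent,
    estimate_pi,
    point_in_polygon,
    polygon_area_ha,
    resolve_month_group,
)
from conftest import make_location

BC, BI, AC, AI = BacipsGroup.BC, BacipsGroup.BI, BacipsGroup.AC, BacipsGroup.AI


def _winding_number_inside(px, py, coords):
    """Independent winding-number oracle (angle-crossing form)."""
    wn = 0
    n = len(coords)
    for i in range(n):
        x1, y1 = coords[i]
        x2, y2 = coords[(i + 1) % n]
        if y1 <= py:
            if y2 > py and (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1) > 0:
                wn += 1
        else:
            if y2 <= py and (x2 - x1) * (py - y1) - (px - x1) * (y2 - y1) < 0:
                wn -= 1
    return wn != 0


class TestGeometry:
    def test_point_in_polygon_basic(self, unit_square):
        assert point_in_polygon((0.5, 0.5), unit_square)
        assert not point_in_polygon((1.5, 0.5), unit_square)
        # boundary counts as inside
        assert point_in_polygon((1.0, 0.5), unit_square)

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError, match="degenerate|fewer"):
            point_in_polygon((0, 0), Polygon([(0, 0), (1, 1), (0, 0), (1, 1)]))

    def test_point_in_polygon_matches_winding_oracle(self, concave_decagon, rng):
        coords = list(concave_decagon.exterior.coords)[:-1]
        pts = rng.uniform(-2, 2, size=(10_000, 2))
        mismatches = 0
        for px, py in pts:
            if concave_decagon.exterior.distance(
                __import__("shapely").geometry.Point(px, py)
            ) < 1e-9:
                continue  # boundary points excluded from the oracle contract
            mismatches += point_in_polygon((px, py), concave_decagon) != (
                _winding_number_inside(px, py, coords)
            )
        assert mismatches == 0

    def test_polygon_area_squares(self, unit_square):
        assert polygon_area_ha(unit_square) == pytest.approx(0.0001)
        assert polygon_area_ha(box(0, 0, 1000, 1000)) == pytest.approx(100.0)

    def test_polygon_area_matches_monte_carlo(self, concave_decagon, rng):
        minx, miny, maxx, maxy = concave_decagon.bounds
        n = 400_000
        pts = rng.uniform((minx, miny), (maxx, maxy), size=(n, 2))
        import shapely

        frac = np.mean(shapely.contains_xy(concave_decagon, pts[:, 0], pts[:, 1]))
        mc_ha = frac * (maxx - minx) * (maxy - miny) / 1e4
        assert polygon_area_ha(concave_decagon) == pytest.approx(mc_ha, rel=0.01)

    def test_self_intersecting_rejected(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])
        with pytest.raises(ValueError, match="invalid|self"):
            polygon_area_ha(bowtie)

    @pytest.mark.parametrize(
        "burned,study,expected",
        [(50412, 123607, 40.8), (22282, 123607, 18.0), (32585, 123607, 26.4), (0, 123607, 0.0)],
    )
    def test_burned_percent(self, burned, study, expected):
        assert burned_percent(burned, study) == expected

    def test_burned_percent_rejects_bad_input(self):
        with pytest.raises(ValueError):
            burned_percent(1.0, 0.0)
        with pytest.raises(ValueError):
            burned_percent(-1.0, 10.0)


class TestAssignGroup:
    def test_four_corners(self, two_fires):
        inside_west = (500.0, 500.0)
        outside = (5000.0, 5000.0)
        # inside a perimeter after its fire started
        assert assign_group(make_location(*inside_west, dt.date(2016, 8, 15)), two_fires) == AI
        # inside a future perimeter before ignition: before-impact
        assert assign_group(make_location(*inside_west, dt.date(2015, 5, 1)), two_fires) == BI
        assert assign_group(make_location(*outside, dt.date(2015, 5, 1)), two_fires) == BC
        # control point after the earliest fire start overall
        assert assign_group(make_location(*outside, dt.date(2016, 9, 1)), two_fires) == AC

    def test_period_from_earliest_containing_fire(self, two_fires):
        # point only inside the later (east) fire: still "before" until that
        # fire starts, even though the west fire already burned
        east_only = (1800.0, 500.0)
        assert assign_group(make_location(*east_only, dt.date(2016, 9, 1)), two_fires) == BI
        assert assign_group(make_location(*east_only, dt.date(2017, 7, 11)), two_fires) == AI
        # overlap strip is governed by the earliest containing fire
        overlap = (950.0, 500.0)
        assert assign_group(make_location(*overlap, dt.date(2016, 12, 1)), two_fires) == AI

    def test_boundary_counts_as_impact(self, two_fires):
        assert assign_group(make_location(1000.0, 500.0, dt.date(2015, 1, 1)), two_fires) == BI

    def test_date_shift_changes_period_only(self, two_fires, rng):
        for _ in range(200):
            x, y = rng.uniform(0, 3000, 2)
            before = assign_group(make_location(x, y, dt.date(2015, 6, 1)), two_fires)
            after = assign_group(make_location(x, y, dt.date(2019, 6, 1)), two_fires)
            assert before.is_impact == after.is_impact
            assert not before.is_after and after.is_after

    def test_empty_fires_rejected(self):
        with pytest.raises(ValueError):
            assign_group(make_location(0, 0), [])


# independent enumeration of the decision-tree hierarchy for all 15 subsets
_EXPECTED_RESOLUTION = {
    frozenset({BC}): BC, frozenset({BI}): BI, frozenset({AC}): AC, frozenset({AI}): AI,
    frozenset({BC, BI}): BI, frozenset({BC, AC}): AC, frozenset({BC, AI}): AI,
    frozenset({BI, AC}): BI, frozenset({BI, AI}): AI, frozenset({AC, AI}): AI,
    frozenset({BC, BI, AC}): BI, frozenset({BC, BI, AI}): AI,
    frozenset({BC, AC, AI}): AI, frozenset({BI, AC, AI}): AI,
    frozenset({BC, BI, AC, AI}): AI,
}


class TestResolveMonthGroup:
    @pytest.mark.parametrize("subset,expected", sorted(_EXPECTED_RESOLUTION.items(), key=str))
    def test_hierarchy(self, subset, expected):
        assert resolve_month_group(subset) == expected

    def test_order_and_duplicate_invariance(self):
        for subset in _EXPECTED_RESOLUTION:
            for perm in itertools.permutations(subset):
                assert resolve_month_group(list(perm) + list(perm)) == _EXPECTED_RESOLUTION[subset]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_month_group(set())


class TestBuildNestRecords:
    def _rows(self):
        return pd.DataFrame(
            [
                # success: found day 0, hatched day 30
                dict(nest_id="n1", bird_id="b1", age_class="adult", x=5000, y=5000,
                     date_found="2015-04-01", date_last_active="2015-04-28",
                     date_fate="2015-05-01", fate="HATCHED"),
                # quick failure before second check: assumed one day
                dict(nest_id="n2", bird_id="b1", age_class="adult", x=5000, y=5000,
                     date_found="2015-04-01", date_last_active="2015-04-01",
                     date_fate="2015-04-04", fate="depredated"),
                # failure: 9 days found->last active
                dict(nest_id="n3", bird_id="b2", age_class="yearling", x=500, y=500,
                     date_found="2015-04-01", date_last_active="2015-04-10",
                     date_fate="2015-04-13", fate="failure"),
                # success spanning 37 days
                dict(nest_id="n4", bird_id="b3", age_class="adult", x=5000, y=5000,
                     date_found="2016-04-05", date_last_active="2016-05-09",
                     date_fate="2016-05-12", fate="successful"),
                # failure found and failed over 2 days
                dict(nest_id="n5", bird_id="b4", age_class="adult", x=5000, y=5000,
                     date_found="2017-05-01", date_last_active="2017-05-03",
                     date_fate="2017-05-06", fate="abandoned"),
            ]
        )

    def test_hand_computed_exposures(self, two_fires):
        records = {r.nest_id: r for r in build_nest_records(self._rows(), two_fires)}
        assert records["n1"].exposure_days == 30
        assert records["n2"].exposure_days == 1
        assert records["n3"].exposure_days == 9
        assert records["n4"].exposure_days == 37
        assert records["n5"].exposure_days == 2
        assert records["n1"].fate == "success" and records["n2"].fate == "failure"

    def test_group_from_location_and_found_date(self, two_fires):
        records = {r.nest_id: r for r in build_nest_records(self._rows(), two_fires)}
        assert records["n3"].group == BI  # inside west fire, pre-fire
        assert records["n1"].group == BC
        assert records["n5"].group == AC  # outside, after first fire

    def test_bad_dates_rejected_with_row_id(self, two_fires):
        rows = self._rows()
        rows.loc[0, "date_fate"] = "2015-03-01"
        with pytest.raises(ValueError, match="n1"):
            build_nest_records(rows, two_fires)

    def test_unknown_fate_rejected(self, two_fires):
        rows = self._rows()
        rows.loc[2, "fate"] = "mystery"
        with pytest.raises(ValueError, match="n3"):
            build_nest_records(rows, two_fires)


class TestBuildAdultHistories:
    def test_decision_tree_applied_within_month(self, two_fires, study_months):
        locs = [
            make_location(5000, 5000, dt.date(2016, 9, 3), "b1"),   # AC
            make_location(1800, 500, dt.date(2016, 9, 20), "b1"),   # BI (east fire not started)
        ]
        (hist,) = build_adult_histories(locs, two_fires, study_months)
        assert hist.months[0].group == BI

    def test_monthly_states_and_death(self, two_fires, study_months):
        locs = [
            make_location(5000, 5000, dt.date(2010, m, 10), "b2") for m in range(1, 10)
        ] + [make_location(5000, 5000, dt.date(2010, 10, 5), "b2", status="dead")]
        (hist,) = build_adult_histories(locs, two_fires, study_months)
        assert len(hist.months) == 10
        assert [m.state for m in hist.months] == ["alive"] * 9 + ["dead"]
        assert all(m.group is not None for m in hist.months)

    def test_gap_months_flagged_missing(self, two_fires, study_months):
        locs = [
            make_location(5000, 5000, dt.date(2010, 1, 10), "b3"),
            make_location(5000, 5000, dt.date(2010, 4, 10), "b3"),
        ]
        (hist,) = build_adult_histories(locs, two_fires, study_months)
        assert [m.group is None for m in hist.months] == [False, True, True, False]
        assert all(m.state == "alive" for m in hist.months)

    def test_yearling_graduates_on_march_first(self, two_fires, study_months):
        locs = [
            make_location(5000, 5000, dt.date(2010, 11, 10), "b4"),
            make_location(5000, 5000, dt.date(2011, 4, 10), "b4"),
        ]
        (hist,) = build_adult_histories(
            locs, two_fires, study_months, capture_ages={"b4": "yearling"}
        )
        ages = [m.age_class for m in hist.months]  # Nov..Apr
        assert ages == ["yearling"] * 4 + ["adult"] * 2

    def test_locations_after_death_rejected(self, two_fires, study_months):
        locs = [
            make_location(5000, 5000, dt.date(2010, 1, 10), "b5"),
            make_location(5000, 5000, dt.date(2010, 2, 10), "b5", status="dead"),
            make_location(5000, 5000, dt.date(2010, 3, 10), "b5"),
        ]
        with pytest.raises(ValueError, match="b5"):
            build_adult_histories(locs, two_fires, study_months)

    def test_decision_tree_rate_on_fixture(self, two_fires, study_months):
        """Months with >= 2 relocations in different groups equal a hand count."""
        locs = []
        for b in range(12):
            bird = f"x{b}"
            locs.append(make_location(5000, 5000, dt.date(2012, 5, 3), bird))
            if b < 4:  # these four also get an impact relocation the same month
                locs.append(make_location(500, 500, dt.date(2012, 5, 20), bird))
        hists = build_adult_histories(locs, two_fires, study_months)
        tree_months = sum(h.months[0].group == BI for h in hists)
        assert tree_months == 4


class TestEstimatePi:
    def _hist(self, bird, entry, groups):
        months = [
            MonthState(state="alive", group=g, age_class="adult") for g in groups
        ]
        return AdultMonthlyHistory(bird_id=bird, entry_month=entry, months=months)

    def test_observed_proportions(self, study_months):
        hists = [self._hist(f"b{i}", 5, [BC]) for i in range(3)]
        hists.append(self._hist("b9", 5, [BI]))
        pi = estimate_pi(hists, study_months)
        assert pi.row(5) == pytest.approx([0.75, 0.25, 0.0, 0.0])

    def test_unit_vector_when_single_group(self, study_months):
        hists = [self._hist(f"b{i}", 3, [AC]) for i in range(5)]
        pi = estimate_pi(hists, study_months)
        assert pi.row(3) == pytest.approx([0.0, 0.0, 1.0, 0.0])

    def test_same_calendar_month_fallback(self, study_months):
        # observations only in month 13 (Feb 2009); month 1 (Feb 2008) borrows them
        hists = [self._hist("b1", 13, [BI, BI])]
        pi = estimate_pi(hists, study_months)
        assert pi.row(1) == pytest.approx([0.0, 1.0, 0.0, 0.0])

    def test_global_fallback(self, study_months):
        hists = [self._hist("b1", 5, [BC]), self._hist("b2", 5, [BI])]
        pi = estimate_pi(hists, study_months)
        # a month whose calendar month was never observed: overall pooled
        assert pi.row(20) == pytest.approx([0.5, 0.5, 0.0, 0.0])

    def test_rows_always_sum_to_one(self, study_months, rng):
        hists = []
        for i in range(25):
            entry = int(rng.integers(0, 120))
            groups = [
                None if rng.random() < 0.4 else BacipsGroup(int(rng.integers(1, 5)))
                for _ in range(int(rng.integers(1, 20)))
            ]
            if all(g is None for g in groups):
                groups[0] = BC
            hists.append(self._hist(f"b{i}", entry, groups))
        pi = estimate_pi(hists, study_months)
        assert np.allclose(pi.weights.sum(axis=1), 1.0, atol=1e-12)
        assert (pi.weights >= 0).all()

    def test_no_observations_rejected(self, study_months):
        hists = [self._hist("b1", 5, [None, None])]
        with pytest.raises(ValueError):
            estimate_pi(hists, study_months)

    def test_pi_matrix_validation(self):
        with pytest.raises(ValueError):
            PiMatrix(np.array([[0.5, 0.4, 0.0, 0.0]]))  # does not sum to 1
        with pytest.raises(ValueError):
            PiMatrix(np.array([[1.2, -0.2, 0.0, 0.0]]))
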