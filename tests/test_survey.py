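"""Site registry, visit validation, existence bookkeeping, region exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dynocc import (
    SiteRegistry,
    apply_region_exclusion,
    assemble_species_data,
    build_existence,
    load_sites,
    write_sites,
)
from dynocc.survey import SurveyDataError, validate_visits

from conftest import toy_sites_frame


class TestSiteRegistry:
    def test_loads_toy_table(self, tmp_path):
        path = tmp_path / "sites.csv"
        toy_sites_frame().to_csv(path, index=False)
        reg = load_sites(path)
        assert reg.n_sites == 3
        assert reg.regions == ("A", "B")
        assert list(reg.is_new) == [False, True, True]

    @pytest.mark.parametrize(
        "column,bad_value,message",
        [
            ("surface_area", 0.0, "surface_area"),
            ("x_km", np.inf, "finite"),
            ("water_fluctuation", 2, "0/1"),
            ("forest_pct_100m", 120.0, "[0, 100]"),
        ],
    )
    def test_rejects_invalid_field(self, column, bad_value, message):
        df = toy_sites_frame()
        df.loc[0, column] = bad_value
        with pytest.raises(SurveyDataError, match="p1"):
            SiteRegistry(df)

    def test_rejects_destruction_before_construction(self):
        df = toy_sites_frame()
        df.loc[1, "destruction_year"] = 2003  # built 2005
        df.loc[1, "destroyed"] = True
        with pytest.raises(SurveyDataError, match="destruction_year"):
            SiteRegistry(df)

    def test_rejects_duplicate_ids(self):
        df = pd.concat([toy_sites_frame()] * 2, ignore_index=True)
        with pytest.raises(SurveyDataError, match="duplicate"):
            SiteRegistry(df)

    def test_old_site_must_not_have_construction_year(self):
        df = toy_sites_frame()
        df.loc[0, "construction_year"] = 2000
        with pytest.raises(SurveyDataError, match="old sites"):
            SiteRegistry(df)

    def test_round_trip(self, toy_sites, tmp_path):
        path = tmp_path / "roundtrip.csv"
        write_sites(toy_sites, path)
        again = load_sites(path)
        pd.testing.assert_frame_equal(
            toy_sites.frame, again.frame, check_dtype=False
        )


class TestExistence:
    years = range(1999, 2020)

    def test_known_construction_year(self, toy_sites, toy_visits):
        E = build_existence(toy_sites, toy_visits, self.years)
        i = 1  # p2 built 2005
        assert not E.E[i, : 2005 - 1999].any()
        assert E.E[i, 2005 - 1999 :].all()

    def test_unknown_construction_uses_first_survey_year(self, toy_sites, toy_visits):
        E = build_existence(toy_sites, toy_visits, self.years)
        i = 2  # p3 new, unknown year, first surveyed 2010
        assert not E.E[i, : 2010 - 1999].any()
        assert E.E[i, 2010 - 1999 :].all()

    def test_old_site_exists_throughout(self, toy_sites, toy_visits):
        E = build_existence(toy_sites, toy_visits, self.years)
        assert E.E[0].all()

    def test_destruction_year_exclusive(self, toy_sites, toy_visits):
        df = toy_sites.frame.copy()
        df.loc[0, "destruction_year"] = 2010
        df.loc[0, "destroyed"] = True
        E = build_existence(SiteRegistry(df), toy_visits, self.years)
        assert E.E[0, : 2010 - 1999].all()
        assert not E.E[0, 2010 - 1999 :].any()

    def test_visit_outside_existence_errors(self, toy_sites, toy_visits):
        df = toy_sites.frame.copy()
        df.loc[1, "construction_year"] = 2008  # p2 surveyed 2006
        df.loc[1, "destruction_year"] = 2012
        df.loc[1, "destroyed"] = True
        with pytest.raises(SurveyDataError, match="outside existence"):
            build_existence(SiteRegistry(df), toy_visits, self.years)

    def test_visit_before_unknown_construction_errors(self, toy_sites, toy_visits):
        df = toy_sites.frame.copy()
        df.loc[1, "construction_year"] = 2008  # p2 surveyed 2006, no destruction
        with pytest.raises(SurveyDataError, match="does not exist"):
            build_existence(SiteRegistry(df), toy_visits, self.years)

    @given(
        start=st.integers(0, 20),
        length=st.integers(0, 20),
        destroyed_after=st.integers(1, 25),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_contiguity_on_random_intervals(self, start, length, destroyed_after):
        """Existence is a contiguous run for any construction/destruction pair."""
        cy = 1999 + start
        dy = cy + destroyed_after
        df = toy_sites_frame().iloc[[1]].reset_index(drop=True)
        df.loc[0, "construction_year"] = max(cy, 1999)
        df.loc[0, "destruction_year"] = dy
        df.loc[0, "destroyed"] = True
        empty = pd.DataFrame({"site_id": [], "year": [], "visit": [], "is_day": []})
        E = build_existence(SiteRegistry(df), empty, self.years)
        on = np.flatnonzero(E.E[0])
        if len(on):
            assert np.array_equal(on, np.arange(on[0], on[-1] + 1))


class TestVisitValidation:
    def test_day_flag_must_match_visit_index(self, toy_sites, toy_visits):
        bad = toy_visits.copy()
        bad.loc[0, "is_day"] = True  # j = 1 flagged as day
        with pytest.raises(SurveyDataError, match="day/night"):
            validate_visits(bad, toy_sites)

    def test_duplicate_visit_rejected(self, toy_sites, toy_visits):
        bad = pd.concat([toy_visits, toy_visits.iloc[[0]]], ignore_index=True)
        with pytest.raises(SurveyDataError, match="duplicate visit"):
            validate_visits(bad, toy_sites)

    def test_extra_visits_rejected_then_truncated(self, toy_sites, toy_visits):
        extra = toy_visits.iloc[[0]].copy()
        extra["visit"] = 4
        extra["is_day"] = False
        bad = pd.concat([toy_visits, extra], ignore_index=True)
        with pytest.raises(SurveyDataError, match="outside protocol"):
            validate_visits(bad, toy_sites)
        ok = validate_visits(bad, toy_sites, truncate_extra_visits=True)
        counts = ok.groupby(["site_id", "year"]).size()
        assert (counts <= 3).all()

    def test_unknown_observer_pooled(self, toy_sites, toy_visits):
        v = toy_visits.copy()
        v.loc[0, "observer_id"] = None
        out = validate_visits(v, toy_sites)
        assert out.loc[0, "observer_id"] == "unknown"


class TestAssembly:
    def test_full_protocol_shape(self, toy_sites, toy_visits):
        data = assemble_species_data(toy_sites, toy_visits, species="sp",
                                     years=range(1999, 2020))
        assert data.y.shape == (3, 3, 21)
        # p1 surveyed 1999 & 2001, all three visits
        assert not np.isnan(data.y[0, :, 0]).any()
        assert np.isnan(data.y[0, :, 1]).all()  # 2000 unsurveyed

    def test_missingness_matches_panel(self, toy_sites, toy_visits):
        data = assemble_species_data(toy_sites, toy_visits, species="sp",
                                     years=range(1999, 2020))
        surveyed = ~np.isnan(data.y)
        expected = {(0, 0), (0, 2), (1, 7), (2, 11)}  # (site, year index)
        got = {(i, t) for i, _, t in zip(*np.nonzero(surveyed))}
        assert got == expected

    def test_row_order_invariance(self, toy_sites, toy_visits):
        shuffled = toy_visits.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = assemble_species_data(toy_sites, toy_visits, species="sp")
        b = assemble_species_data(toy_sites, shuffled, species="sp")
        np.testing.assert_array_equal(
            np.nan_to_num(a.y, nan=-1), np.nan_to_num(b.y, nan=-1)
        )
        np.testing.assert_array_equal(a.observer_idx, b.observer_idx)

    def test_long_format_detections_merge(self, toy_sites, toy_visits):
        structure = toy_visits.drop(columns=["detected"])
        det = toy_visits.assign(species="sp")[
            ["site_id", "year", "visit", "species", "detected"]
        ]
        data = assemble_species_data(toy_sites, structure, det, species="sp")
        assert np.nansum(data.y) == toy_visits["detected"].sum()


class TestRegionExclusion:
    def _make(self, n_det_a, n_det_b):
        """Two-region dataset with the given numbers of detection sites."""
        rng = np.random.default_rng(0)
        rows = []
        for region, count in (("A", 15), ("B", 15)):
            for i in range(count):
                rows.append({
                    "site_id": f"{region}{i}", "region": region,
                    "is_new": False, "construction_year": pd.NA,
                    "destruction_year": pd.NA, "destroyed": False,
                    "x_km": rng.uniform(0, 5), "y_km": rng.uniform(0, 5),
                    "elevation": 400.0, "surface_area": 100.0,
                    "water_fluctuation": 0, "forest_pct_100m": 20.0,
                    "road_area_1km": 0.0,
                })
        sites = SiteRegistry(pd.DataFrame(rows))
        visits = []
        for region, n_det in (("A", n_det_a), ("B", n_det_b)):
            for i in range(15):
                visits.append({
                    "site_id": f"{region}{i}", "year": 2000, "visit": 1,
                    "is_day": False, "observer_id": "o1",
                    "detected": int(i < n_det),
                })
        return assemble_species_data(sites, pd.DataFrame(visits), species="sp",
                                     years=range(1999, 2003))

    def test_boundary_eleven_retained_ten_excluded(self):
        data = apply_region_exclusion(self._make(11, 10))
        assert data.regions_included == ("A",)
        assert data.n_sites == 15

    def test_all_excluded_errors(self):
        with pytest.raises(SurveyDataError, match="no data for species"):
            apply_region_exclusion(self._make(2, 3))

    def test_idempotent(self):
        once = apply_region_exclusion(self._make(12, 11))
        twice = apply_region_exclusion(once)
        assert once.regions_included == twice.regions_included
        np.testing.assert_array_equal(
            np.nan_to_num(once.y, nan=-1), np.nan_to_num(twice.y, nan=-1)
        )

    def test_matches_brute_force_count(self, tiny_fixture):
        data = tiny_fixture.data
        kept = apply_region_exclusion(data, min_sites=1).regions_included
        # brute force: count detection sites per region from the raw array
        survivors = []
        for region in data.sites.regions:
            count = 0
            for i in range(data.n_sites):
                if data.sites.frame["region"].iloc[i] != region:
                    continue
                if np.nansum(data.y[i]) > 0:
                    count += 1
            if count > 1:
                survivors.append(region)
        assert kept == tuple(survivors)
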