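"""Manly design-III selection ratios, CIs, chi-square test, point snapping."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from tealmig._geo import LocalProjection
from tealmig.evaluate import chisq_type1_rate, ci_coverage, se_vs_bootstrap
from tealmig.selection import (ManlySelectionModel, SiteTable, assign_ecoregion,
                               assign_point_class, classify_selection, loglik_chisq,
                               manly_wi_design3, site_table)
from tealmig.sma import HabitatMap

H2 = ("h0", "h1")


def two_site_tables():
    """The hand-computable two-site, two-habitat configuration:
    site 1 pi=(.5,.5) u=(8,2); site 2 pi=(.25,.75) u=(5,5)."""
    return [
        SiteTable("s1", [0.5, 0.5], [8, 2], area_m2=1.0, habitats=H2),
        SiteTable("s2", [0.25, 0.75], [5, 5], area_m2=1.0, habitats=H2),
    ]


class TestManlyRatios:
    def test_hand_computed_two_site_example(self):
        fr = manly_wi_design3(two_site_tables()).set_index("habitat")
        # w1 = (8+5) / (10*0.5 + 10*0.25) = 13/7.5; w2 = (2+5)/(10*0.5+10*0.75)
        assert fr.loc["h0", "w"] == pytest.approx(13 / 7.5, abs=1e-12)
        assert fr.loc["h1", "w"] == pytest.approx(7 / 12.5, abs=1e-12)

    def test_proportional_use_gives_unit_ratios(self):
        tables = [
            SiteTable("s1", [0.4, 0.6], [4, 6], area_m2=1.0, habitats=H2),
            SiteTable("s2", [0.2, 0.8], [2, 8], area_m2=1.0, habitats=H2),
        ]
        fr = manly_wi_design3(tables)
        np.testing.assert_allclose(fr["w"], 1.0)

    def test_expected_use_weighted_mean_is_one(self):
        tables = two_site_tables()
        fr = manly_wi_design3(tables).set_index("habitat")
        e = np.array([tb.u_total * tb.pi for tb in tables]).sum(axis=0)
        u_tot = sum(tb.u_total for tb in tables)
        conserved = float(np.sum(fr["w"].to_numpy() * e / u_tot))
        assert conserved == pytest.approx(1.0, abs=1e-9)

    def test_lcl_truncated_at_zero(self):
        tables = [
            SiteTable("s1", [0.9, 0.1], [10, 0], area_m2=1.0, habitats=H2),
            SiteTable("s2", [0.9, 0.1], [9, 1], area_m2=1.0, habitats=H2),
            SiteTable("s3", [0.9, 0.1], [10, 0], area_m2=1.0, habitats=H2),
        ]
        fr = manly_wi_design3(tables)
        assert (fr["lcl"] >= 0).all()

    def test_single_contributing_site_flagged(self):
        tables = [
            SiteTable("s1", [0.98, 0.02, 0.0], [5, 5, 0], area_m2=1.0, habitats=("a", "b", "c")),
            SiteTable("s2", [0.95, 0.0, 0.05], [9, 0, 1], area_m2=1.0, habitats=("a", "b", "c")),
        ]
        fr = manly_wi_design3(tables).set_index("habitat")
        assert fr.loc["b", "call"] == "single-site-unreliable"
        assert fr.loc["c", "call"] == "single-site-unreliable"

    def test_unused_scarce_habitat_undetermined(self):
        # available in <1% of stratum area, never used
        tables = [
            SiteTable("s1", [0.995, 0.005], [10, 0], area_m2=1.0, habitats=H2),
            SiteTable("s2", [0.999, 0.001], [10, 0], area_m2=1.0, habitats=H2),
        ]
        fr = manly_wi_design3(tables).set_index("habitat")
        assert fr.loc["h1", "call"] == "undetermined"

    def test_all_zero_use_fatal(self):
        tables = [SiteTable("s1", [0.5, 0.5], [0, 0], habitats=H2)]
        with pytest.raises(ValueError):
            ManlySelectionModel(tables)

    def test_stratified_fit_includes_pooled_and_per_stratum(self):
        tables = two_site_tables() + two_site_tables()
        res = ManlySelectionModel(tables, strata=["A", "A", "B", "B"]).fit()
        assert set(res.frame["stratum"]) == {"all", "A", "B"}
        # duplicated strata reproduce the pooled estimate
        a = res.stratum("A").set_index("habitat")["w"]
        b = res.stratum("B").set_index("habitat")["w"]
        pd.testing.assert_series_equal(a, b)


class TestClassifySelection:
    @pytest.mark.parametrize(
        "lcl,ucl,expected",
        [(1.2, 3.0, "selected"), (0.1, 0.8, "avoided"), (0.9, 1.4, "neutral")],
    )
    def test_rule(self, lcl, ucl, expected):
        assert classify_selection(lcl, ucl) == expected


class TestLogLikChisq:
    def test_zero_when_use_equals_expectation(self):
        tables = [SiteTable("s1", [0.4, 0.6], [4, 6], habitats=H2)]
        g, df, p = loglik_chisq(tables)
        assert g == pytest.approx(0.0, abs=1e-12)
        assert df == 1

    def test_matches_term_by_term_hand_computation(self):
        tables = two_site_tables()
        g, df, _ = loglik_chisq(tables)
        expect = 2 * (
            8 * np.log(8 / 5.0) + 2 * np.log(2 / 5.0)
            + 5 * np.log(5 / 2.5) + 5 * np.log(5 / 7.5)
        )
        assert g == pytest.approx(expect, abs=1e-12)
        assert df == 2

    def test_type1_error_rate_near_alpha(self):
        rate = chisq_type1_rate(seed=5, n_reps=2000)
        assert 0.03 <= rate <= 0.07


class TestEstimatorCalibration:
    def test_ci_coverage_of_true_ratios(self):
        cov = ci_coverage(seed=11, n_reps=500)
        assert 0.90 <= cov <= 0.98

    def test_se_agrees_with_bootstrap(self):
        out = se_vs_bootstrap(seed=3, n_boot=2000)
        assert (out["rel_diff"] <= 0.15).all()


def toy_map():
    """One wetland square with a dry surround, in a local meter frame
    converted to lon/lat for the public interface."""
    proj = LocalProjection(-115.0, 35.0, "aeqd")
    wet = proj.unproject(box(0, 0, 1000, 1000))
    wet2 = proj.unproject(box(1080, 0, 2000, 1000))
    dry = proj.unproject(box(-3000, -3000, 3000, 3000)).difference(wet).difference(wet2)
    hm = HabitatMap([wet, wet2, dry],
                    ["wet agriculture", "natural wetland", "dry nonhabitat"],
                    ["private", "public", "private"])
    return proj, hm


class TestPointAssignment:
    def test_point_inside_wetland(self):
        proj, hm = toy_map()
        lon, lat = proj.inverse(500.0, 500.0)
        assert assign_point_class(float(lon), float(lat), hm, proj) == "wet agriculture"

    def test_snap_to_nearest_wetland(self):
        proj, hm = toy_map()
        # 50 m from wet agriculture's edge, 30 m from natural wetland's edge
        lon, lat = proj.inverse(1050.0, 500.0)
        assert assign_point_class(float(lon), float(lat), hm, proj) == "natural wetland"

    def test_beyond_snap_radius_dry(self):
        proj, hm = toy_map()
        lon, lat = proj.inverse(500.0, -1500.0)
        assert assign_point_class(float(lon), float(lat), hm, proj) == "dry nonhabitat"


class TestSiteTable:
    def test_half_covered_square_availability(self, small_cohort):
        from tealmig.evaluate import run_cohort_segmentation

        # use a real detected site but an artificial half/half map over it
        _, _, sub, sites = run_cohort_segmentation(small_cohort)[0]
        s = sites[0]
        proj = LocalProjection(*s.centroid, "aeqd")
        frame = proj.project(s.polygon)
        minx, miny, maxx, maxy = frame.bounds
        left = box(minx - 100, miny - 100, (minx + maxx) / 2, maxy + 100)
        right = box((minx + maxx) / 2, miny - 100, maxx + 100, maxy + 100)
        hm = HabitatMap(
            [proj.unproject(left), proj.unproject(right)],
            ["natural wetland", "dry nonhabitat"],
        )
        tb = site_table(s, sub, hm)
        i = list(tb.habitats).index("natural wetland")
        assert tb.pi[i] == pytest.approx(0.5, abs=0.02)
        assert tb.pi.sum() == pytest.approx(1.0, abs=1e-9)
        assert tb.u_total == s.n_use_fixes


class TestEcoregionAssignment:
    def _regions(self):
        return (
            [box(-125, 40, -110, 50), box(-125, 30, -110, 40)],
            ["Great Plains", "Northwestern Forested Mountains"],
        )

    def test_direct_containment(self, small_cohort):
        polys, names = self._regions()
        from tealmig.stopovers import StopoverSite

        s = StopoverSite("x", "b", np.array([0]), np.array([0]),
                         pd.Timestamp("2018-09-01", tz="UTC"),
                         pd.Timestamp("2018-09-02", tz="UTC"), (-120.0, 45.0))
        assert assign_ecoregion(s, polys, names) == "Great Plains"

    def test_merge_into_cold_deserts(self):
        polys, names = self._regions()
        from tealmig.stopovers import StopoverSite

        s = StopoverSite("x", "b", np.array([0]), np.array([0]),
                         pd.Timestamp("2018-09-01", tz="UTC"),
                         pd.Timestamp("2018-09-02", tz="UTC"), (-120.0, 35.0))
        assert assign_ecoregion(s, polys, names) == "Cold Deserts"

    def test_unassigned_when_outside_all_regions(self):
        polys, names = self._regions()
        from tealmig.stopovers import StopoverSite

        s = StopoverSite("x", "b", np.array([0]), np.array([0]),
                         pd.Timestamp("2018-09-01", tz="UTC"),
                         pd.Timestamp("2018-09-02", tz="UTC"), (0.0, 0.0))
        assert assign_ecoregion(s, polys, names) is None
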