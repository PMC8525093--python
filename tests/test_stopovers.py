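"""Nearest-neighbor labeling, flight filtering, site building and buffering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from tealmig._geo import geodesic_area_m2, haversine_km
from tealmig.evaluate import run_cohort_segmentation
from tealmig.stopovers import (build_sites, buffer_site, filter_sites, flag_flight,
                               label_fixes, nn_distance_2day)
from tealmig.tracks import fix_speeds

from conftest import make_track

KM_PER_DEG_EQ = 111.195


def eq_track(hours, east_km, bird="b"):
    lons = np.asarray(east_km, float) / KM_PER_DEG_EQ
    return make_track(bird, hours, lons, np.zeros(len(lons)))


def nn_bruteforce(track, window_h=48.0):
    """O(n^2) all-pairs oracle."""
    n = len(track)
    t_h = track.t.asi8 / 3.6e12
    out = np.full(n, np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and abs(t_h[i] - t_h[j]) <= window_h:
                d = haversine_km(track.lon[i], track.lat[i], track.lon[j], track.lat[j])
                out[i] = min(out[i], float(d))
    return out


class TestNNDistance:
    def test_coincident_pair_zero(self):
        trk = eq_track([0, 1], [5, 5])
        np.testing.assert_allclose(nn_distance_2day(trk), [0, 0])

    def test_isolated_fix_infinite(self):
        trk = eq_track([0, 100], [0, 300])
        assert np.isinf(nn_distance_2day(trk)).all()

    def test_matches_bruteforce_on_random_tracks(self):
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = rng.integers(5, 40)
            hours = np.sort(rng.uniform(0, 200, n))
            hours += np.arange(n) * 1e-6  # enforce strictly increasing
            trk = make_track("b", hours, rng.uniform(-1, 1, n) - 115, rng.uniform(-1, 1, n) + 35)
            np.testing.assert_allclose(nn_distance_2day(trk), nn_bruteforce(trk))

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(3, 15), st.integers(0, 10_000))
    def test_matches_bruteforce_property(self, n, seed):
        rng = np.random.default_rng(seed)
        hours = np.sort(rng.uniform(0, 150, n)) + np.arange(n) * 1e-6
        trk = make_track("b", hours, rng.uniform(-0.5, 0.5, n), rng.uniform(-0.5, 0.5, n))
        np.testing.assert_allclose(nn_distance_2day(trk), nn_bruteforce(trk))


class TestLabels:
    @pytest.mark.parametrize("nn,expected", [(0.0, True), (5.0, True), (5.1, False)])
    def test_threshold_inclusive(self, nn, expected):
        assert label_fixes(np.array([nn]))[0] == expected

    @pytest.mark.parametrize("v,expected", [(20.0, True), (0.0, False), (10.0, False)])
    def test_flight_strict(self, v, expected):
        assert flag_flight(np.array([v]))[0] == expected

    def test_undefined_speed_not_flight(self):
        assert not flag_flight(np.array([np.nan]))[0]


def cc_oracle(track, stopover, link_km=5.0, link_h=48.0):
    """Connected components under the (<=5 km, <=48 h) relation."""
    idx = np.flatnonzero(stopover)
    m = len(idx)
    t_h = track.t.asi8 / 3.6e12
    rows, cols = [], []
    for a in range(m):
        for b in range(a + 1, m):
            i, j = idx[a], idx[b]
            if abs(t_h[i] - t_h[j]) <= link_h:
                d = haversine_km(track.lon[i], track.lat[i], track.lon[j], track.lat[j])
                if d <= link_km:
                    rows.append(a)
                    cols.append(b)
    g = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(m, m))
    n_comp, labels = connected_components(g, directed=False)
    comps = [tuple(idx[labels == k]) for k in range(n_comp)]
    return sorted(comps)


class TestBuildSites:
    def _sites(self, trk):
        nn = nn_distance_2day(trk)
        stop = label_fixes(nn)
        fly = flag_flight(fix_speeds(trk))
        return build_sites(trk, stop, fly), stop, fly

    def test_two_distant_clusters_two_sites(self):
        hours = list(np.arange(0, 24, 2)) + list(np.arange(30, 54, 2))
        east = [0 + 0.1 * (i % 3) for i in range(12)] + [100 + 0.1 * (i % 3) for i in range(12)]
        trk = eq_track(hours, east)
        sites, stop, _ = self._sites(trk)
        assert len(sites) == 2
        assert sorted(tuple(s.fix_index) for s in sites) == cc_oracle(trk, stop)

    def test_no_stopover_fixes_no_sites(self):
        trk = eq_track([0, 24, 48], [0, 150, 300])
        sites, _, _ = self._sites(trk)
        assert sites == []

    def test_revisit_after_three_days_two_sites(self):
        hours = [0, 1, 2] + [74, 75, 76]  # same spot, 3-day absence
        trk = eq_track(hours, [0, 0.1, 0.2, 0, 0.1, 0.2])
        sites, _, _ = self._sites(trk)
        assert len(sites) == 2

    def test_matches_connected_components_on_cohort(self, small_cohort):
        for _, _, sub, _ in run_cohort_segmentation(small_cohort):
            nn = nn_distance_2day(sub)
            stop = label_fixes(nn)
            fly = flag_flight(fix_speeds(sub))
            sites = build_sites(sub, stop, fly)
            assert sorted(tuple(s.fix_index) for s in sites) == cc_oracle(sub, stop)


class TestFilterSites:
    def _candidates(self, hours, east, fly_mask=None):
        trk = eq_track(hours, east)
        stop = np.ones(len(trk), bool)
        fly = np.zeros(len(trk), bool) if fly_mask is None else np.asarray(fly_mask)
        return filter_sites(build_sites(trk, stop, fly), trk), trk

    def test_two_nonflight_fixes_rejected(self):
        kept, _ = self._candidates([0, 4], [0, 0.1])
        assert kept == []

    def test_three_fixes_spanning_three_hours_retained(self):
        kept, _ = self._candidates([0, 1.5, 3.0], [0, 0.1, 0.2])
        assert len(kept) == 1

    def test_all_flying_rejected(self):
        kept, _ = self._candidates([0, 1, 2, 3, 4], [0, 0.1, 0.2, 0.3, 0.4],
                                   fly_mask=[True] * 5)
        assert kept == []


class TestBufferSite:
    def test_single_point_disk_area(self):
        trk = eq_track([0, 1, 2, 4], [0, 0, 0, 0])
        stop = np.ones(4, bool)
        sites = build_sites(trk, stop, np.zeros(4, bool))
        poly = buffer_site(sites[0], trk)
        area_km2 = geodesic_area_m2(poly) / 1e6
        assert area_km2 == pytest.approx(np.pi * 25.0, rel=0.01)

    def test_two_points_5km_apart_union_area(self):
        trk = eq_track([0, 1, 2, 3], [0, 0, 4.99, 4.99])
        stop = np.ones(4, bool)
        sites = build_sites(trk, stop, np.zeros(4, bool))
        poly = buffer_site(sites[0], trk)
        disk = np.pi * 25.0
        area_km2 = geodesic_area_m2(poly) / 1e6
        assert disk < area_km2 < 2 * disk

    def test_use_fixes_inside_polygon(self, small_cohort):
        from shapely.geometry import Point

        for _, _, sub, sites in run_cohort_segmentation(small_cohort):
            for s in sites:
                for i in s.use_index:
                    assert s.polygon.covers(Point(sub.lon[i], sub.lat[i]))


class TestHistogramShape:
    def test_nn_distribution_bimodal_with_gap_at_5km(self, small_cohort):
        """Stopover and migratory movement separate: the pooled 2-day NN
        distance histogram has mass below 5 km and above 5 km with a clear
        gap spanning the threshold."""
        vals = []
        for _, _, sub, _ in run_cohort_segmentation(small_cohort):
            nn = nn_distance_2day(sub)
            vals.extend(nn[np.isfinite(nn)])
        vals = np.asarray(vals)
        assert (vals <= 5).sum() > 50 and (vals > 5).sum() > 20
        # the gap: nothing between the stopover dispersion and the flight legs
        assert ((vals > 3.6) & (vals < 5.5)).sum() == 0

    def test_site_count_stable_under_timestamp_stable_sort(self, small_cohort):
        for _, _, sub, sites in run_cohort_segmentation(small_cohort):
            order = np.argsort(sub.t.asi8, kind="stable")
            resorted = sub.slice(order)
            nn = nn_distance_2day(resorted)
            rs = build_sites(resorted, label_fixes(nn), flag_flight(fix_speeds(resorted)))
            assert len(filter_sites(rs, resorted)) == len(sites)
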