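"""Event detection, site clustering, founding groups, shortstop rule."""

import numpy as np
import pandas as pd
import pytest

from shortstop import site_detection as sdet
from shortstop.geo import GeoPoint, haversine_km, project_aeqd
from shortstop.synthetic_data import make_fixture

BREEDING = GeoPoint(43.87, -89.23)
CENTRE = GeoPoint(36.0, -86.0)


def _relocs(rows):
    df = pd.DataFrame(rows, columns=["bird_id", "date", "lat", "lon"])
    df["date"] = pd.to_datetime(df["date"])
    return df.sort_values(["bird_id", "date"]).reset_index(drop=True)


def _meta(birds, hatch=2000):
    return pd.DataFrame({"bird_id": birds, "hatch_year": [hatch] * len(birds)})


def _lon_at_km(lat, lon, km):
    return lon + km / (111.2 * np.cos(np.radians(lat)))


class TestWinterYear:
    def test_label_is_year_of_opening_november(self):
        dates = pd.Series(pd.to_datetime(
            ["2005-11-01", "2006-04-30", "2006-05-01", "2006-10-31", "2006-07-15"]))
        wy = sdet.assign_winter_year(dates)
        assert list(wy[:2]) == [2005, 2005]
        assert wy[2:].isna().all()


class TestDetectEvents:
    def test_minimal_qualifying_pair(self):
        r = _relocs([("a", "2005-12-01", 33.0, -85.0),
                     ("a", "2005-12-21", 33.0, _lon_at_km(33, -85.0, 5))])
        es = sdet.detect_bird_winter_events(r, _meta(["a"]))
        assert len(es.events) == 1
        assert es.events.iloc[0]["span_days"] == 20

    def test_short_span_discarded(self):
        r = _relocs([("a", "2005-12-01", 33.0, -85.0),
                     ("a", "2005-12-11", 33.0, _lon_at_km(33, -85.0, 5))])
        es = sdet.detect_bird_winter_events(r, _meta(["a"]))
        assert len(es.events) == 0

    def test_matches_bruteforce_single_linkage(self, rng):
        """Two 30-day clouds 300 km apart: membership must equal a
        brute-force all-pairs connected-components oracle."""
        rows = []
        for i in range(50):
            cloud = i % 2
            lat = 32.0 + cloud * 2.7          # ~300 km apart
            day = 1 + (i // 2) % 30
            rows.append(("a", f"2007-12-{day:02d}",
                         lat + rng.normal(0, 0.02), -85.0 + rng.normal(0, 0.02)))
        r = _relocs(rows)
        es = sdet.detect_bird_winter_events(r, _meta(["a"]))
        assert len(es.events) == 2

        # oracle: brute-force union-find over all observation pairs
        wy = sdet.assign_winter_year(r["date"])
        pts = r[wy.notna()]
        lab = list(range(len(pts)))

        def find(i):
            while lab[i] != i:
                i = lab[i]
            return i

        la = pts["lat"].to_numpy()
        lo = pts["lon"].to_numpy()
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                if haversine_km(la[i], lo[i], la[j], lo[j]) < 10.0:
                    lab[find(j)] = find(i)
        oracle_sizes = sorted(np.unique([find(i) for i in range(len(pts))],
                                        return_counts=True)[1])
        assert sorted(es.events["n_obs"]) == oracle_sizes

    def test_unsorted_input_rejected(self):
        r = _relocs([("a", "2005-12-21", 33.0, -85.0),
                     ("a", "2005-12-01", 33.0, -85.0)])
        r = r.iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="sorted"):
            sdet.detect_bird_winter_events(r, _meta(["a"]))

    def test_no_winter_observations_is_empty_not_error(self):
        r = _relocs([("a", "2005-07-01", 43.0, -89.0)])
        es = sdet.detect_bird_winter_events(r, _meta(["a"]))
        assert len(es.events) == 0

    def test_first_year_birds_excluded(self):
        r = _relocs([("a", "2005-12-01", 33.0, -85.0),
                     ("a", "2005-12-21", 33.0, -85.0)])
        es = sdet.detect_bird_winter_events(r, _meta(["a"], hatch=2005))
        assert len(es.events) == 0


class TestPreprocess:
    def test_exact_duplicates_dropped_and_near_dups_collapsed(self):
        r = _relocs([("a", "2005-12-01", 33.0, -85.0),
                     ("a", "2005-12-01", 33.0, -85.0),           # exact dup
                     ("a", "2005-12-02", 33.0, -85.0),
                     ("a", "2005-12-02", 33.005, -85.0)])        # <1 km apart
        out = sdet.preprocess_relocations(r)
        assert len(out) == 2
        day2 = out[out["date"] == "2005-12-02"]
        assert float(day2["lat"].iloc[0]) == pytest.approx(33.0025)


class TestSouthernmost:
    def test_southern_event_wins_and_tie_breaks_by_arrival(self):
        events = pd.DataFrame({
            "event_id": [0, 1, 2, 3],
            "bird_id": ["a", "a", "b", "b"],
            "winter_year": [2005] * 4,
            "lat": [35.0, 30.0, 33.0, 33.0],
            "lon": [-85, -85, -85, -83],
            "first_date": pd.to_datetime(["2005-11-05", "2005-12-01",
                                          "2005-12-10", "2005-11-20"]),
        })
        sel = sdet.select_southernmost(events)
        assert set(sel["event_id"]) == {1, 3}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sdet.select_southernmost(pd.DataFrame(columns=["bird_id"]))


def _event_set_from_points(points, rng=None):
    """Build an EventSet of single-observation-pair events at given centroids."""
    events = []
    members = {}
    for i, (lat, lon, year) in enumerate(points):
        events.append({"event_id": i, "bird_id": f"b{i}", "winter_year": year,
                       "age": 3, "lat": lat, "lon": lon,
                       "first_date": pd.Timestamp(year, 12, 1),
                       "last_date": pd.Timestamp(year, 12, 20),
                       "span_days": 19, "n_obs": 2})
        members[i] = (np.array([lat, lat]), np.array([lon, lon]))
    return sdet.EventSet(events=pd.DataFrame(events), members=members)


def _bruteforce_partition(event_set, method):
    ev = event_set.events
    n = len(ev)
    lab = list(range(n))

    def find(i):
        while lab[i] != i:
            i = lab[i]
        return i

    thresh = {"pairwise_10km": 10.0, "centroid_20km": 20.0,
              "centroid_10km": 10.0}[method]
    for i in range(n):
        for j in range(i + 1, n):
            if method == "pairwise_10km":
                li, oi = event_set.members[int(ev["event_id"].iloc[i])]
                lj, oj = event_set.members[int(ev["event_id"].iloc[j])]
                d = haversine_km(li[:, None], oi[:, None], lj[None, :], oj[None, :]).min()
            else:
                d = haversine_km(ev["lat"].iloc[i], ev["lon"].iloc[i],
                                 ev["lat"].iloc[j], ev["lon"].iloc[j])
            if d < thresh:
                lab[find(j)] = find(i)
    roots = [find(i) for i in range(n)]
    groups = {}
    for i, r in enumerate(roots):
        groups.setdefault(r, set()).add(int(ev["event_id"].iloc[i]))
    return sorted(map(frozenset, groups.values()), key=min)


class TestClusterSites:
    def test_far_event_is_separate_site(self):
        es = _event_set_from_points([(33.0, -85.0, 2005),
                                     (33.0, _lon_at_km(33, -85.0, 5), 2006),
                                     (37.5, -85.0, 2006)])
        sites, events = sdet.cluster_sites(es, "pairwise_10km", BREEDING, CENTRE)
        assert len(sites) == 2

    def test_single_linkage_chain_merges(self):
        es = _event_set_from_points([
            (33.0, -85.0, 2005),
            (33.0, _lon_at_km(33, -85.0, 8), 2005),
            (33.0, _lon_at_km(33, -85.0, 16), 2006)])
        sites, _ = sdet.cluster_sites(es, "pairwise_10km", BREEDING, CENTRE)
        assert len(sites) == 1

    @pytest.mark.parametrize("method", sdet.CLUSTER_METHODS)
    def test_matches_bruteforce_union_find(self, method, rng):
        pts = [(float(32 + rng.uniform(0, 2)),
                float(-86 + rng.uniform(0, 2)),
                int(rng.integers(2004, 2010))) for _ in range(40)]
        es = _event_set_from_points(pts)
        sites, events = sdet.cluster_sites(es, method, BREEDING, CENTRE)
        got = (events.groupby("site_id")["event_id"]
               .apply(lambda s: frozenset(int(x) for x in s)))
        got = sorted(got, key=min)
        assert got == _bruteforce_partition(es, method)

    def test_partition_invariant_to_event_order(self, rng):
        pts = [(float(31 + rng.uniform(0, 3)), float(-87 + rng.uniform(0, 3)),
                int(rng.integers(2004, 2010))) for _ in range(30)]
        es = _event_set_from_points(pts)
        sites1, ev1 = sdet.cluster_sites(es, "centroid_20km", BREEDING, CENTRE)
        perm = rng.permutation(len(pts))
        es2 = sdet.EventSet(events=es.events.iloc[perm].reset_index(drop=True),
                            members=es.members)
        sites2, ev2 = sdet.cluster_sites(es2, "centroid_20km", BREEDING, CENTRE)
        pd.testing.assert_frame_equal(sites1, sites2)
        merged = ev1[["event_id", "site_id"]].merge(
            ev2[["event_id", "site_id"]], on="event_id")
        assert (merged["site_id_x"] == merged["site_id_y"]).all()

    def test_no_event_lost_or_duplicated(self, default_analysis):
        sites = default_analysis["sites"]
        selected = default_analysis["selected_events"]
        assert sites["n_events"].sum() == len(selected)

    def test_unknown_method_rejected(self):
        es = _event_set_from_points([(33.0, -85.0, 2005), (34.0, -85.0, 2005)])
        with pytest.raises(ValueError, match="unknown"):
            sdet.cluster_sites(es, "voronoi", BREEDING, CENTRE)

    def test_all_methods_agree_on_separated_sites(self, default_dataset):
        """With inter-site gaps > 50 km the three linkage definitions
        give identical partitions (robustness of site identification)."""
        from shortstop.pipeline import site_model_rows_for

        counts = {}
        for method in sdet.CLUSTER_METHODS:
            out = site_model_rows_for(default_dataset, linkage_method=method)
            key = (out["selected_events"]
                   .sort_values("event_id")["site_id"].to_numpy())
            counts[method] = (len(out["sites"]), key)
        base_n, base_key = counts["pairwise_10km"]
        for method, (n, key) in counts.items():
            assert n == base_n
            # same partition up to labelling: compare co-membership
            assert len(set(zip(base_key, key))) == base_n


class TestFoundingGroups:
    def test_max_age_and_size(self):
        sites = pd.DataFrame({"site_id": [0], "lat": [33.0], "lon": [-85.0],
                              "first_use_year": [2006], "n_events": [3],
                              "distance_km": [1200.0]})
        events = pd.DataFrame({
            "site_id": [0, 0, 0, 0], "winter_year": [2006, 2006, 2006, 2007],
            "bird_id": ["a", "b", "c", "d"]})
        meta = pd.DataFrame({"bird_id": list("abcd"),
                             "hatch_year": [2004, 2001, 1999, 2000]})
        g = sdet.founding_groups(sites, events, meta)
        assert g.iloc[0]["max_age"] == 7
        assert g.iloc[0]["size"] == 3
        assert "d" not in g.iloc[0]["bird_ids"]

    def test_missing_hatch_year_named_in_error(self):
        sites = pd.DataFrame({"site_id": [0], "lat": [33.0], "lon": [-85.0],
                              "first_use_year": [2006], "n_events": [1],
                              "distance_km": [1200.0]})
        events = pd.DataFrame({"site_id": [0], "winter_year": [2006],
                               "bird_id": ["ghost"]})
        with pytest.raises(ValueError, match="ghost"):
            sdet.founding_groups(sites, events, pd.DataFrame(
                {"bird_id": ["a"], "hatch_year": [2000]}))

    def test_generator_ground_truth_recovered(self, default_dataset,
                                              default_analysis):
        """Founding groups detected from relocations must match the
        generator's records site for site."""
        truth = default_dataset.truth.sites
        groups = default_analysis["groups"]
        sites = default_analysis["sites"]
        assert len(sites) == len(truth)
        merged = sites.merge(groups, on="site_id")
        for _, row in merged.iterrows():
            d = haversine_km(truth["lat"], truth["lon"], row["lat"], row["lon"])
            t = truth.iloc[int(np.argmin(d))]
            assert d.min() < 5.0
            assert row["first_use_year"] == t["first_use_year"]
            assert row["max_age"] == t["max_age"]
            assert row["bird_ids"] == t["founder_ids"]


class TestClassifyShortstop:
    def _record(self, dist_km):
        # place a point at the requested planar distance due south
        lat = BREEDING.lat - dist_km / 111.2
        ev = pd.DataFrame({"bird_id": ["a"], "winter_year": [2010], "age": [4],
                           "lat": [lat], "lon": [BREEDING.lon]})
        # refine latitude so the AEQD distance is exact
        bx, by = project_aeqd(BREEDING.lat, BREEDING.lon, CENTRE)
        for _ in range(40):
            x, y = project_aeqd(float(ev["lat"].iloc[0]),
                                float(ev["lon"].iloc[0]), CENTRE)
            d = float(np.hypot(x - bx, y - by))
            ev["lat"] += (d - dist_km) / 111.2
        return ev

    @pytest.mark.parametrize("dist, expected", [(1199.9, True), (1200.0, False)])
    def test_strict_threshold(self, dist, expected):
        rec = sdet.classify_shortstop(self._record(dist), BREEDING, CENTRE)
        assert rec["migration_distance_km"].iloc[0] == pytest.approx(dist, abs=0.05)
        assert bool(rec["shortstopped"].iloc[0]) is expected

    def test_latitude_extremes_straddle_threshold(self):
        """A Florida Gulf Coast site is a full migration; an Indiana-
        latitude site is a shortstop."""
        ev = pd.DataFrame({"bird_id": ["fl", "in"], "winter_year": [2010, 2010],
                           "age": [4, 4], "lat": [28.6, 41.2],
                           "lon": [-82.7, -86.5]})
        rec = sdet.classify_shortstop(ev, BREEDING, CENTRE)
        by_bird = rec.set_index("bird_id")
        assert not by_bird.loc["fl", "shortstopped"]
        assert by_bird.loc["fl", "migration_distance_km"] > 1200
        assert by_bird.loc["in", "shortstopped"]
        assert by_bird.loc["in", "migration_distance_km"] < 1200


class TestFixtureDatasets:
    def test_two_site_chain_collapses_to_one_site(self):
        ds = make_fixture("two-site-chain")
        out_events = sdet.detect_bird_winter_events(ds.relocations, ds.metadata)
        assert len(out_events.events) == 3
        sites, _ = sdet.cluster_sites(out_events, "pairwise_10km",
                                      BREEDING, CENTRE)
        assert len(sites) == 1

    def test_tie_latitude_keeps_earlier_event(self):
        ds = make_fixture("tie-latitude")
        es = sdet.detect_bird_winter_events(ds.relocations, ds.metadata)
        assert len(es.events) == 2
        sel = sdet.select_southernmost(es.events)
        assert len(sel) == 1
        assert sel.iloc[0]["first_date"] == ds.relocations["date"].min()

    def test_single_founder_group(self):
        ds = make_fixture("single-founder")
        es = sdet.detect_bird_winter_events(ds.relocations, ds.metadata)
        sites, events = sdet.cluster_sites(es, "pairwise_10km", BREEDING, CENTRE)
        g = sdet.founding_groups(sites, events, ds.metadata)
        assert len(g) == 1
        assert g.iloc[0]["size"] == 1
        assert g.iloc[0]["max_age"] == 4
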