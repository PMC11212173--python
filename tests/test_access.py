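"""Road graph, travel times, barriers, snapping and service-area bands."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from mcpr.access import (
    DEFAULT_BREAKS,
    RoadSegment,
    apply_barriers,
    assign_band,
    build_graph,
    district_access_report,
    edge_travel_minutes,
    snap_facilities,
    travel_time_surface,
)
from mcpr.errors import ConfigurationError, McprError


def seg(sid, a, b, cls="tertiary"):
    return RoadSegment(segment_id=sid, coords=[a, b], road_class=cls)


class TestEdgeTravelMinutes:
    @pytest.mark.parametrize(
        "length,cls,minutes",
        [
            (60.0, "tertiary", 60.0),    # 1 h at 60 km/h
            (60.0, "tracks", 180.0),     # 3 h at 20 km/h
            (60.0, "primary", 30.0),     # 0.5 h at 120 km/h
            (60.0, "secondary", 45.0),
            (60.0, "residential", 90.0),
            (10.0, "tracks", 30.0),
        ],
    )
    def test_speed_table(self, length, cls, minutes):
        assert edge_travel_minutes(length, cls) == pytest.approx(minutes)

    def test_zero_length_rejected(self):
        with pytest.raises(ConfigurationError):
            edge_travel_minutes(0.0, "primary")

    def test_unknown_class_rejected(self):
        with pytest.raises(ConfigurationError):
            edge_travel_minutes(5.0, "footpath")


class TestBuildGraph:
    def test_shared_endpoint_merges_nodes(self):
        g = build_graph([seg("a", (0, 0), (1, 0)), seg("b", (1, 0), (2, 0))])
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2

    def test_parallel_edges_collapse_to_cheaper(self):
        g = build_graph(
            [seg("slow", (0, 0), (1, 0), "tracks"), seg("fast", (0, 0), (1, 0), "primary")]
        )
        assert g.number_of_edges() == 1
        (u, v, d), = g.edges(data=True)
        assert d["segment_id"] == "fast"

    def test_weights_equal_length_speed_arithmetic(self):
        segments = [
            seg("a", (0, 0), (30, 0), "tertiary"),     # 30 km @60 -> 30 min
            seg("b", (30, 0), (30, 40), "primary"),    # 40 km @120 -> 20 min
            seg("c", (30, 40), (30, 50), "tracks"),    # 10 km @20 -> 30 min
            seg("d", (30, 50), (32, 50), "residential"),  # 2 km @40 -> 3 min
        ]
        g = build_graph(segments)
        minutes = sorted(d["minutes"] for *_, d in g.edges(data=True))
        assert minutes == pytest.approx([3.0, 20.0, 30.0, 30.0])

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigurationError):
            build_graph([])


def square_lake(x0, y0, x1, y1):
    return Polygon([(x0, y0), (x1, y0), (x1, y1), (x0, y1)])


class TestBarriers:
    def two_path_graph(self):
        # routes 0->2: direct tertiary 60 km (60 min) or detour via 1
        return build_graph(
            [
                seg("direct", (0, 0), (60, 0), "tertiary"),
                seg("up", (0, 0), (0, 30), "tertiary"),
                seg("across", (0, 30), (60, 30), "tertiary"),
                seg("down", (60, 30), (60, 0), "tertiary"),
            ]
        )

    def test_lake_forces_alternative_route(self):
        g = self.two_path_graph()
        direct = nx.shortest_path_length(g, 0, 1, weight="minutes")
        g2 = apply_barriers(g, [square_lake(20, -5, 40, 5)])
        detour = nx.shortest_path_length(g2, 0, 1, weight="minutes")
        assert direct == pytest.approx(60.0)
        assert detour == pytest.approx(120.0)
        assert len(g2.graph["removed_edges"]) == 1

    def test_no_intersection_identity(self):
        g = self.two_path_graph()
        g2 = apply_barriers(g, [square_lake(200, 200, 210, 210)])
        assert g2.number_of_edges() == g.number_of_edges()
        assert g2.graph["removed_edges"] == []

    def test_lake_on_cut_edge_disconnects(self):
        g = build_graph([seg("a", (0, 0), (10, 0)), seg("b", (10, 0), (20, 0))])
        g2 = apply_barriers(g, [square_lake(12, -1, 18, 1)])
        assert not nx.has_path(g2, 0, 2)

    def test_removal_never_decreases_travel_time(self, rng):
        g = self.two_path_graph()
        g = snap_facilities(g, [("f", Point(60, 0))])
        before = travel_time_surface(g).minutes
        g2 = apply_barriers(g, [square_lake(20, -5, 40, 5)])
        after = travel_time_surface(g2).minutes
        for node in before:
            assert after[node] >= before[node] - 1e-9


class TestSnapFacilities:
    def base(self):
        return build_graph([seg("a", (0, 0), (60, 0)), seg("b", (60, 0), (120, 0))])

    def test_on_edge_snaps_at_zero(self):
        g = snap_facilities(self.base(), [("f", Point(30, 0))])
        assert g.graph["facilities"]["f"]["snap_km"] == pytest.approx(0.0)

    def test_beyond_tolerance_unlocated(self):
        g = snap_facilities(self.base(), [("f", Point(30, 20))], tolerance_km=15)
        assert g.graph["facilities"] == {}
        assert g.graph["unlocated_facilities"] == ["f"]

    def test_mixed_accounting(self):
        facs = [("f0", Point(10, 1)), ("f1", Point(100, -2)), ("f2", Point(30, 99))]
        g = snap_facilities(self.base(), facs)
        assert sorted(g.graph["facilities"]) == ["f0", "f1"]
        assert g.graph["unlocated_facilities"] == ["f2"]

    def test_edge_split_preserves_total_minutes(self):
        g = self.base()
        total_before = sum(d["minutes"] for *_, d in g.edges(data=True))
        g2 = snap_facilities(g, [("f", Point(15, 3))])
        total_after = sum(d["minutes"] for *_, d in g2.edges(data=True))
        assert total_after == pytest.approx(total_before)
        assert g2.number_of_nodes() == g.number_of_nodes() + 1

    def test_projection_at_endpoint_reuses_node(self):
        g = snap_facilities(self.base(), [("f", Point(60, 5))])
        assert g.number_of_nodes() == 3
        assert g.graph["facilities"]["f"]["node"] == 1


class TestTravelTimeSurface:
    def path_graph(self):
        # chain 0-1-2-3-4 with 20/40/100/90-minute tertiary edges
        return build_graph(
            [
                seg("a", (0, 0), (20, 0)),
                seg("b", (20, 0), (60, 0)),
                seg("c", (60, 0), (160, 0)),
                seg("d", (160, 0), (250, 0)),
            ]
        )

    def test_facility_node_zero_minutes_band_one(self):
        g = snap_facilities(self.path_graph(), [("f", Point(0, 0))])
        s = travel_time_surface(g)
        assert s.minutes[0] == 0.0
        assert s.band[0] == 1

    def test_distances_match_bruteforce_path_enumeration(self):
        g = snap_facilities(self.path_graph(), [("f", Point(20, 0))])
        s = travel_time_surface(g)
        for node in g.nodes:
            best = math.inf
            for path in nx.all_simple_paths(g, 1, node):
                cost = sum(
                    g[a][b]["minutes"] for a, b in zip(path, path[1:])
                )
                best = min(best, cost)
            if node == 1:
                best = 0.0
            assert s.minutes[node] == pytest.approx(best)

    def test_band_boundaries(self):
        assert assign_band(30.0) == 1
        assert assign_band(30.000001) == 2
        assert assign_band(240.0) == 6
        assert assign_band(241.0) == "unreachable"
        assert assign_band(math.inf) == "unreachable"

    def test_bands_partition_zero_to_240(self, rng):
        # half-open intervals are disjoint and jointly cover (0, 240]
        edges = [0.0] + list(DEFAULT_BREAKS)
        for m in rng.random(300) * 240.0:
            b = assign_band(float(m))
            assert isinstance(b, int)
            lo, hi = edges[b - 1], edges[b]
            assert (lo < m <= hi) or (b == 1 and m == 0.0)

    def test_no_facilities_raises(self):
        with pytest.raises(McprError):
            travel_time_surface(self.path_graph())

    def test_adding_facility_never_increases_times(self):
        g1 = snap_facilities(self.path_graph(), [("f", Point(0, 0))])
        s1 = travel_time_surface(g1)
        g2 = snap_facilities(g1, [("g", Point(250, 0))])
        s2 = travel_time_surface(g2)
        assert all(s2.minutes[n] <= s1.minutes[n] + 1e-9 for n in g1.nodes)


class TestExhaustiveOracleSmallGraphs:
    def test_random_graphs_up_to_8_nodes(self, rng):
        """Dijkstra result equals exhaustive path enumeration on every
        random connected graph with <= 8 nodes."""
        for trial in range(25):
            n = int(rng.integers(3, 9))
            g = nx.Graph()
            for i in range(n):
                g.add_node(i, pos=(float(i), 0.0))
            # random spanning tree plus extra edges
            nodes = list(rng.permutation(n))
            for a, b in zip(nodes, nodes[1:]):
                g.add_edge(int(a), int(b), minutes=float(rng.uniform(1, 50)))
            for _ in range(n):
                a, b = rng.integers(0, n, 2)
                if a != b and not g.has_edge(int(a), int(b)):
                    g.add_edge(int(a), int(b), minutes=float(rng.uniform(1, 50)))
            sources = [0]
            g.graph["facilities"] = {"f": {"node": 0, "snap_km": 0.0}}
            s = travel_time_surface(g)
            for node in g.nodes:
                best = 0.0 if node == 0 else min(
                    (
                        sum(g[a][b]["minutes"] for a, b in zip(p, p[1:]))
                        for p in nx.all_simple_paths(g, 0, node)
                    ),
                    default=math.inf,
                )
                assert s.minutes[node] == pytest.approx(best)


class TestDistrictReport:
    def test_all_women_at_facility(self):
        g = build_graph([seg("a", (0, 0), (30, 0))])
        g = snap_facilities(g, [("f", Point(0, 0)), ("g", Point(30, 0))])
        s = travel_time_surface(g)
        demand = pd.DataFrame(
            {"district_id": [0, 1], "x": [0.0, 30.0], "y": [0.0, 0.0]}
        )
        rep = district_access_report(s, g, demand)
        assert (rep["band_1_share"] == 1.0).all()
        assert (rep["median_minutes"] == 0.0).all()

    def test_remote_district_flagged(self):
        g = build_graph(
            [
                seg("a", (0, 0), (30, 0)),
                seg("far", (30, 0), (130, 0), "tracks"),  # 100 km @20 -> 300 min
            ]
        )
        g = snap_facilities(g, [("f", Point(0, 0))])
        s = travel_time_surface(g)
        demand = pd.DataFrame(
            {"district_id": [0, 1], "x": [0.0, 130.0], "y": [0.0, 0.0]}
        )
        rep = district_access_report(s, g, demand).set_index("district_id")
        assert not rep.loc[0, "flag_over_240"]
        assert rep.loc[1, "flag_over_240"]

    def test_band_shares_sum_to_one(self, rng):
        g = build_graph(
            [seg(f"s{i}", (20.0 * i, 0), (20.0 * (i + 1), 0)) for i in range(10)]
        )
        g = snap_facilities(g, [("f", Point(0, 0))])
        s = travel_time_surface(g)
        demand = pd.DataFrame(
            {
                "district_id": rng.integers(0, 3, 30),
                "x": rng.random(30) * 200,
                "y": np.zeros(30),
                "n_women": rng.integers(1, 20, 30).astype(float),
            }
        )
        rep = district_access_report(s, g, demand)
        share_cols = [c for c in rep.columns if c.endswith("_share")]
        assert rep[share_cols].sum(axis=1).to_numpy() == pytest.approx(
            np.ones(len(rep)), abs=1e-9
        )


class TestFixedAssignedTimes:
    def test_fixed_class_minutes_override_formula(self):
        from mcpr.access import ASSIGNED_CLASS_MINUTES

        segments = [
            seg("a", (0, 0), (5, 0), "primary"),
            seg("b", (5, 0), (9, 0), "tracks"),
        ]
        g = build_graph(segments, fixed_class_minutes=ASSIGNED_CLASS_MINUTES)
        minutes = sorted(d["minutes"] for *_, d in g.edges(data=True))
        assert minutes == [30.0, 180.0]  # length-independent

    def test_band_polygons_cover_reached_edges(self):
        from mcpr.access import band_polygons

        g = build_graph(
            [seg("a", (0, 0), (20, 0)), seg("b", (20, 0), (200, 0), "tracks")]
        )
        g = snap_facilities(g, [("f", Point(0, 0))])
        s = travel_time_surface(g)
        polys = band_polygons(s, g, buffer_km=1.0)
        assert 1 in polys and polys[1].contains(Point(10, 0))
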