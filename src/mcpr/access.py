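"""Road-network travel-time accessibility to health facilities.

Builds an undirected road graph from classed segments in a planar km
coordinate system, weights each edge by driving minutes
(length / class speed * 60), removes edges crossing lake barriers, snaps
facilities to the network within a search tolerance (15 km by default),
computes per-node minimum driving time to the nearest facility, and
assigns each node to one of six non-overlapping time bands
(0-30, 30-45, 45-60, 60-90, 90-180, 180-240 minutes; beyond 240 minutes
or disconnected counts as unreachable).

Roads are treated as undirected with symmetric speeds, so "driving towards
the facility" coincides with the reverse direction used by the multi-source
shortest path.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon

from .errors import ConfigurationError, McprError

__all__ = [
    "ROAD_CLASSES",
    "DEFAULT_SPEEDS",
    "DEFAULT_BREAKS",
    "RoadSegment",
    "AccessSurface",
    "edge_travel_minutes",
    "build_graph",
    "apply_barriers",
    "snap_facilities",
    "travel_time_surface",
    "assign_band",
    "band_polygons",
    "district_access_report",
    "ASSIGNED_CLASS_MINUTES",
]

ROAD_CLASSES = ("primary", "secondary", "tertiary", "residential", "tracks")

#: national speed per road class, km/h
DEFAULT_SPEEDS: dict[str, float] = {
    "primary": 120.0,
    "secondary": 80.0,
    "tertiary": 60.0,
    "residential": 40.0,
    "tracks": 20.0,
}

#: upper bounds (minutes) of the six service-area bands
DEFAULT_BREAKS: tuple[float, ...] = (30.0, 45.0, 60.0, 90.0, 180.0, 240.0)

#: fixed assigned driving time per class (minutes), an alternative edge
#: weighting for fidelity experiments against workflows that assign one
#: time per road type instead of the length-dependent formula
ASSIGNED_CLASS_MINUTES: dict[str, float] = {
    "primary": 30.0,
    "secondary": 45.0,
    "tertiary": 60.0,
    "residential": 90.0,
    "tracks": 180.0,
}


@dataclass
class RoadSegment:
    """A polyline road segment in planar km coordinates."""

    segment_id: str
    coords: list[tuple[float, float]]
    road_class: str

    @property
    def length_km(self) -> float:
        return LineString(self.coords).length

    @property
    def geometry(self) -> LineString:
        return LineString(self.coords)


def edge_travel_minutes(
    length_km: float, road_class: str, speeds: dict[str, float] | None = None
) -> float:
    """Driving minutes along a segment: length / class speed * 60."""
    speeds = DEFAULT_SPEEDS if speeds is None else speeds
    if length_km <= 0:
        raise ConfigurationError(f"segment length must be positive, got {length_km}")
    if road_class not in speeds:
        raise ConfigurationError(f"unknown road class: {road_class!r}")
    speed = speeds[road_class]
    if speed <= 0:
        raise ConfigurationError(f"non-positive speed for {road_class!r}")
    return length_km / speed * 60.0


def _node_key(xy: tuple[float, float], eps: float) -> tuple[int, int]:
    return (round(xy[0] / eps), round(xy[1] / eps))


def build_graph(
    segments: list[RoadSegment],
    speeds: dict[str, float] | None = None,
    eps: float = 1e-6,
    fixed_class_minutes: dict[str, float] | None = None,
) -> nx.Graph:
    """Assemble the undirected road graph.

    Endpoints equal within ``eps`` km share a node; each segment becomes
    one edge weighted by its driving minutes.  Parallel edges between the
    same node pair collapse to the cheaper one.  Node ids are deterministic
    (insertion order of first appearance).

    ``fixed_class_minutes`` replaces the length/speed weighting with one
    fixed time per road class (e.g. :data:`ASSIGNED_CLASS_MINUTES`).
    """
    if not segments:
        raise ConfigurationError("no road segments")
    g = nx.Graph()
    key_to_id: dict[tuple[int, int], int] = {}

    def node_id(xy):
        key = _node_key(xy, eps)
        if key not in key_to_id:
            nid = len(key_to_id)
            key_to_id[key] = nid
            g.add_node(nid, pos=(float(xy[0]), float(xy[1])))
        return key_to_id[key]

    for seg in segments:
        a = node_id(seg.coords[0])
        b = node_id(seg.coords[-1])
        if a == b:
            continue  # degenerate loop after rounding
        if fixed_class_minutes is not None:
            if seg.road_class not in fixed_class_minutes:
                raise ConfigurationError(f"unknown road class: {seg.road_class!r}")
            minutes = fixed_class_minutes[seg.road_class]
        else:
            minutes = edge_travel_minutes(seg.length_km, seg.road_class, speeds)
        if g.has_edge(a, b) and g[a][b]["minutes"] <= minutes:
            continue
        g.add_edge(
            a,
            b,
            minutes=minutes,
            road_class=seg.road_class,
            segment_id=seg.segment_id,
            geometry=seg.geometry,
        )
    g.graph["speeds"] = dict(DEFAULT_SPEEDS if speeds is None else speeds)
    g.graph["facilities"] = {}
    g.graph["unlocated_facilities"] = []
    g.graph["removed_edges"] = []
    return g


def apply_barriers(graph: nx.Graph, lakes: list[Polygon]) -> nx.Graph:
    """Remove every edge whose geometry intersects a lake interior.

    Nodes are kept (they may become isolated); removed edges are logged on
    the graph under ``removed_edges``.
    """
    g = graph.copy()
    removed = []
    for a, b, data in list(g.edges(data=True)):
        line = data.get("geometry") or LineString(
            [g.nodes[a]["pos"], g.nodes[b]["pos"]]
        )
        for lake in lakes:
            if line.intersects(lake) and not line.touches(lake):
                removed.append((a, b, data.get("segment_id")))
                g.remove_edge(a, b)
                break
    g.graph["removed_edges"] = list(g.graph.get("removed_edges", [])) + removed
    return g


def snap_facilities(
    graph: nx.Graph,
    facilities: list[tuple[str, Point]],
    tolerance_km: float = 15.0,
) -> nx.Graph:
    """Attach each facility to the nearest point on the nearest edge.

    The edge is split at the perpendicular projection (a new node), and the
    facility is recorded on the graph as ``facility_id -> node`` with its
    snap distance.  Facilities farther than ``tolerance_km`` from every
    edge are listed under ``unlocated_facilities`` and take no part in
    routing.
    """
    g = graph.copy()
    g.graph["facilities"] = dict(g.graph.get("facilities", {}))
    g.graph["unlocated_facilities"] = list(g.graph.get("unlocated_facilities", []))
    next_id = (max(g.nodes) + 1) if g.number_of_nodes() else 0
    for fid, pt in facilities:
        best = None
        for a, b, data in g.edges(data=True):
            line = data.get("geometry") or LineString(
                [g.nodes[a]["pos"], g.nodes[b]["pos"]]
            )
            d = line.distance(pt)
            if best is None or d < best[0]:
                best = (d, a, b, data, line)
        if best is None or best[0] > tolerance_km:
            g.graph["unlocated_facilities"].append(fid)
            continue
        d, a, b, data, line = best
        proj = line.interpolate(line.project(pt))
        pa = Point(g.nodes[a]["pos"])
        frac = line.project(proj) / line.length if line.length > 0 else 0.0
        # snap to an existing endpoint when the projection lands on one
        if proj.distance(pa) < 1e-9 or frac <= 1e-9:
            node = a
        elif proj.distance(Point(g.nodes[b]["pos"])) < 1e-9 or frac >= 1 - 1e-9:
            node = b
        else:
            node = next_id
            next_id += 1
            g.add_node(node, pos=(proj.x, proj.y))
            minutes = data["minutes"]
            g.remove_edge(a, b)
            common = {
                "road_class": data.get("road_class"),
                "segment_id": data.get("segment_id"),
            }
            ls = list(line.coords)
            g.add_edge(a, node, minutes=minutes * frac,
                       geometry=LineString([ls[0], (proj.x, proj.y)]), **common)
            g.add_edge(node, b, minutes=minutes * (1 - frac),
                       geometry=LineString([(proj.x, proj.y), ls[-1]]), **common)
        g.graph["facilities"][fid] = {"node": node, "snap_km": float(d)}
    return g


def assign_band(minutes: float, breaks: tuple[float, ...] = DEFAULT_BREAKS):
    """Band index 1..len(breaks) for a travel time; beyond the last break
    (or infinite) -> ``"unreachable"``.

    Band 1 is [0, breaks[0]]; band i>1 is (breaks[i-2], breaks[i-1]].
    """
    if not math.isfinite(minutes):
        return "unreachable"
    if minutes < 0:
        raise ConfigurationError("negative travel time")
    for i, ub in enumerate(breaks, start=1):
        if minutes <= ub:
            return i
    return "unreachable"


@dataclass
class AccessSurface:
    """Minimum driving minutes to the nearest facility, per graph node."""

    minutes: dict[int, float]
    band: dict[int, object]
    breaks: tuple[float, ...] = DEFAULT_BREAKS
    facility_nodes: list[int] = field(default_factory=list)


def travel_time_surface(
    graph: nx.Graph, breaks: tuple[float, ...] = DEFAULT_BREAKS
) -> AccessSurface:
    """Multi-source shortest driving time from every node to the nearest
    located facility, with service-area band labels."""
    fac = graph.graph.get("facilities", {})
    sources = sorted({info["node"] for info in fac.values()})
    if not sources:
        raise McprError("no located facilities on the network")
    dist = nx.multi_source_dijkstra_path_length(graph, sources, weight="minutes")
    minutes = {}
    band = {}
    for node in graph.nodes:
        m = dist.get(node, math.inf)
        minutes[node] = m
        band[node] = assign_band(m, breaks)
    return AccessSurface(minutes=minutes, band=band, breaks=tuple(breaks),
                         facility_nodes=sources)


def _nearest_node(graph: nx.Graph, pt: Point) -> int:
    pos = nx.get_node_attributes(graph, "pos")
    items = sorted(pos.items())
    arr = np.array([xy for _, xy in items])
    ids = [nid for nid, _ in items]
    d2 = (arr[:, 0] - pt.x) ** 2 + (arr[:, 1] - pt.y) ** 2
    return ids[int(np.argmin(d2))]


def district_access_report(
    surface: AccessSurface,
    graph: nx.Graph,
    demand_points: pd.DataFrame,
    flag_minutes: float = 240.0,
) -> pd.DataFrame:
    """Per-district share of women in each time band and the median time.

    ``demand_points`` needs columns ``district_id``, ``x``, ``y`` and
    optionally ``n_women`` (weight, default 1); each point is served by its
    nearest network node.  Districts whose weighted median travel time
    exceeds ``flag_minutes`` are flagged.
    """
    pts = demand_points.copy()
    if "n_women" not in pts.columns:
        pts["n_women"] = 1.0
    pts["node"] = [
        _nearest_node(graph, Point(x, y)) for x, y in zip(pts["x"], pts["y"])
    ]
    pts["minutes"] = [surface.minutes[n] for n in pts["node"]]
    pts["band"] = [surface.band[n] for n in pts["node"]]
    band_labels = list(range(1, len(surface.breaks) + 1)) + ["unreachable"]
    rows = []
    for did, grp in pts.groupby("district_id"):
        w = grp["n_women"].to_numpy(float)
        total = w.sum()
        shares = {
            f"band_{lbl}_share": float(w[grp["band"] == lbl].sum() / total)
            for lbl in band_labels
        }
        finite = np.isfinite(grp["minutes"].to_numpy(float))
        med = _weighted_median(
            grp["minutes"].to_numpy(float), w
        )
        rows.append(
            {
                "district_id": did,
                "n_women": total,
                **shares,
                "median_minutes": med,
                "flag_over_240": bool(med > flag_minutes) if math.isfinite(med) else True,
                "any_unreachable": bool((~finite).any()),
            }
        )
    return pd.DataFrame(rows)


def band_polygons(
    surface: AccessSurface, graph: nx.Graph, buffer_km: float = 2.0
) -> dict:
    """Dissolved service-area polygon per band: the union of buffered
    edge geometries whose worse endpoint falls in the band.  Geometry is
    indicative (the contract is the per-node band labels)."""
    from shapely.ops import unary_union

    polys = {}
    for b in range(1, len(surface.breaks) + 1):
        geoms = []
        for a, c, data in graph.edges(data=True):
            worse = max(surface.minutes[a], surface.minutes[c])
            if assign_band(worse, surface.breaks) == b:
                line = data.get("geometry") or LineString(
                    [graph.nodes[a]["pos"], graph.nodes[c]["pos"]]
                )
                geoms.append(line.buffer(buffer_km))
        if geoms:
            polys[b] = unary_union(geoms)
    return polys


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    idx = int(np.searchsorted(cw, 0.5 * cw[-1]))
    return float(v[min(idx, len(v) - 1)])
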