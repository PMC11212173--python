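"""Toy planar geography for the accessibility analysis.

Generates a connected road grid with the five national road classes,
health-facility points (optionally a fraction deliberately placed beyond
the snap tolerance to exercise unlocated-facility accounting), lake
polygons overlapping some roads, and a rectangular district partition.
Coordinates are kilometres in a flat plane: travel times need only lengths
and class speeds, so no geodesy is involved.

All layers round-trip through GeoJSON FeatureCollections (roads as
LineStrings with a ``class`` property, facilities as Points, lakes and
districts as Polygons); exports are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon, mapping, shape

from .access import ROAD_CLASSES, RoadSegment
from .simulate import SimulationConfig

__all__ = [
    "ToyGeography",
    "generate_geography",
    "geography_to_geojson",
    "geography_from_geojson",
    "write_geojson",
]


@dataclass
class ToyGeography:
    districts: list[tuple[int, Polygon]]
    roads: list[RoadSegment]
    facilities: list[tuple[str, Point]]
    lakes: list[Polygon] = field(default_factory=list)


_CLASS_WEIGHTS = {"primary": 0.08, "secondary": 0.17, "tertiary": 0.25,
                  "residential": 0.30, "tracks": 0.20}


def generate_geography(config: SimulationConfig) -> ToyGeography:
    """Build the synthetic road/facility/lake/district layers.

    The road network is an ``nx x ny`` rectangular grid of segments with
    per-segment classes drawn from fixed weights (always connected before
    barriers).  ``unlocated_fraction`` of facilities is pushed outside the
    snap tolerance; the rest sit within ``snap_jitter_km`` of a road.
    Districts tile the road bounding box as a rectangle grid with
    ``n_districts`` cells.
    """
    geo = config.geography
    rng = config.child_seed("geography")
    nx_, ny, cell = geo.grid_nx, geo.grid_ny, geo.cell_km

    roads: list[RoadSegment] = []
    classes = list(_CLASS_WEIGHTS)
    probs = np.array([_CLASS_WEIGHTS[c] for c in classes])
    sid = 0
    for j in range(ny):
        for i in range(nx_):
            x, y = i * cell, j * cell
            for dx, dy in ((1, 0), (0, 1)):
                if i + dx < nx_ and j + dy < ny:
                    cls = rng.choice(classes, p=probs)
                    roads.append(
                        RoadSegment(
                            segment_id=f"r{sid}",
                            coords=[(x, y), ((i + dx) * cell, (j + dy) * cell)],
                            road_class=str(cls),
                        )
                    )
                    sid += 1

    width, height = (nx_ - 1) * cell, (ny - 1) * cell
    n_unloc = int(round(geo.unlocated_fraction * geo.n_facilities))
    facilities: list[tuple[str, Point]] = []
    for k in range(geo.n_facilities):
        if k < geo.n_facilities - n_unloc:
            seg = roads[rng.integers(len(roads))]
            t = rng.random()
            (x0, y0), (x1, y1) = seg.coords[0], seg.coords[-1]
            px = x0 + t * (x1 - x0) + rng.uniform(-geo.snap_jitter_km, geo.snap_jitter_km)
            py = y0 + t * (y1 - y0) + rng.uniform(-geo.snap_jitter_km, geo.snap_jitter_km)
        else:
            # beyond any road by more than the 15 km default tolerance
            px = width + 40.0 + 10.0 * rng.random()
            py = height + 40.0 + 10.0 * rng.random()
        facilities.append((f"f{k}", Point(float(px), float(py))))

    lakes = []
    for _ in range(geo.n_lakes):
        cx = rng.uniform(0.2, 0.8) * width
        cy = rng.uniform(0.2, 0.8) * height
        lakes.append(Point(cx, cy).buffer(geo.lake_radius_km, quad_segs=8))

    districts = []
    ncols = int(np.ceil(np.sqrt(config.n_districts)))
    nrows = int(np.ceil(config.n_districts / ncols))
    dw, dh = (width or cell) / ncols, (height or cell) / nrows
    did = 0
    for r in range(nrows):
        for c in range(ncols):
            if did >= config.n_districts:
                break
            poly = Polygon(
                [
                    (c * dw, r * dh),
                    ((c + 1) * dw, r * dh),
                    ((c + 1) * dw, (r + 1) * dh),
                    (c * dw, (r + 1) * dh),
                ]
            )
            districts.append((did, poly))
            did += 1
    return ToyGeography(districts=districts, roads=roads, facilities=facilities, lakes=lakes)


def _round_coords(obj, ndigits=6):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(o, ndigits) for o in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def _feature(geom, props):
    gj = mapping(geom)
    gj = {**gj, "coordinates": _round_coords(gj["coordinates"])}
    return {"type": "Feature", "geometry": gj, "properties": props}


def geography_to_geojson(geo: ToyGeography) -> dict[str, dict]:
    """Serialize the four layers to GeoJSON FeatureCollections."""
    return {
        "roads": {
            "type": "FeatureCollection",
            "features": [
                _feature(seg.geometry, {"segment_id": seg.segment_id, "class": seg.road_class})
                for seg in geo.roads
            ],
        },
        "facilities": {
            "type": "FeatureCollection",
            "features": [
                _feature(pt, {"facility_id": fid}) for fid, pt in geo.facilities
            ],
        },
        "lakes": {
            "type": "FeatureCollection",
            "features": [_feature(poly, {}) for poly in geo.lakes],
        },
        "districts": {
            "type": "FeatureCollection",
            "features": [
                _feature(poly, {"district_id": did}) for did, poly in geo.districts
            ],
        },
    }


def geography_from_geojson(layers: dict[str, dict]) -> ToyGeography:
    """Rebuild a :class:`ToyGeography` from the four FeatureCollections."""
    roads = [
        RoadSegment(
            segment_id=f["properties"]["segment_id"],
            coords=[tuple(c) for c in f["geometry"]["coordinates"]],
            road_class=f["properties"]["class"],
        )
        for f in layers["roads"]["features"]
    ]
    facilities = [
        (f["properties"]["facility_id"], shape(f["geometry"]))
        for f in layers["facilities"]["features"]
    ]
    lakes = [shape(f["geometry"]) for f in layers["lakes"]["features"]]
    districts = [
        (f["properties"]["district_id"], shape(f["geometry"]))
        for f in layers["districts"]["features"]
    ]
    return ToyGeography(districts=districts, roads=roads, facilities=facilities, lakes=lakes)


def write_geojson(collection: dict, path) -> None:
    """Write a FeatureCollection deterministically (sorted keys, fixed
    separators, LF newlines)."""
    with open(path, "w", newline="\n") as fh:
        json.dump(collection, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
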