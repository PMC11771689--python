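"""Vector domain objects (fences, focal regions, corridors) and GeoJSON I/O.

All geometries live in one projected planar frame in meters; GeoJSON files
written here carry projected coordinates, not longitude/latitude.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Polygon, mapping, shape
from shapely.strtree import STRtree


@dataclass
class FenceNetwork:
    """A set of fence polylines with per-line ids.

    Lines are independent polylines; crossings need not be noded — downstream
    parcel detection nodes the arrangement itself.
    """

    lines: list[LineString]
    ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.ids:
            self.ids = [f"fence_{i:04d}" for i in range(len(self.lines))]
        if len(self.ids) != len(self.lines):
            raise ValueError("ids and lines length mismatch")
        for ln in self.lines:
            if not ln.is_simple:
                raise ValueError("self-crossing fence polyline")

    def __len__(self) -> int:
        return len(self.lines)

    @property
    def total_length(self) -> float:
        return float(sum(ln.length for ln in self.lines))

    def tree(self) -> STRtree:
        return STRtree(self.lines)

    def crosses(self, segment: LineString, tree: STRtree | None = None) -> bool:
        """True if the segment intersects any fence line."""
        tree = tree or self.tree()
        for idx in tree.query(segment):
            if self.lines[idx].intersects(segment):
                return True
        return False


@dataclass
class FocalRegion:
    """Named polygon contracted to a zero-resistance supernode in the circuit."""

    name: str
    geometry: Polygon


@dataclass
class Corridor:
    """Candidate restoration corridor: a centerline buffered by width/2."""

    corridor_id: str
    centerline: LineString

    def buffered(self, width_m: float) -> Polygon:
        if width_m <= 0:
            raise ValueError("corridor width must be positive")
        return self.centerline.buffer(width_m / 2.0, cap_style="flat")


# -- GeoJSON ----------------------------------------------------------------

def _feature_collection(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path: str | Path, geometries, properties: list[dict] | None = None) -> Path:
    path = Path(path)
    properties = properties or [{} for _ in geometries]
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties, strict=True)
    ]
    path.write_text(json.dumps(_feature_collection(feats), indent=1))
    return path


def read_geojson(path: str | Path) -> tuple[list, list[dict]]:
    data = json.loads(Path(path).read_text())
    geoms, props = [], []
    for feat in data["features"]:
        geoms.append(shape(feat["geometry"]))
        props.append(feat.get("properties") or {})
    return geoms, props


def write_fences(network: FenceNetwork, path: str | Path) -> Path:
    return write_geojson(path, network.lines, [{"id": i} for i in network.ids])


def read_fences(path: str | Path) -> FenceNetwork:
    geoms, props = read_geojson(path)
    ids = [p.get("id", f"fence_{i:04d}") for i, p in enumerate(props)]
    return FenceNetwork(lines=list(geoms), ids=ids)


def write_focal_regions(regions: list[FocalRegion], path: str | Path) -> Path:
    return write_geojson(path, [r.geometry for r in regions], [{"name": r.name} for r in regions])


def read_focal_regions(path: str | Path) -> list[FocalRegion]:
    geoms, props = read_geojson(path)
    return [FocalRegion(name=p.get("name", f"focal_{i}"), geometry=g) for i, (g, p) in enumerate(zip(geoms, props))]


def write_corridors(corridors: list[Corridor], path: str | Path) -> Path:
    return write_geojson(
        path, [c.centerline for c in corridors], [{"id": c.corridor_id} for c in corridors]
    )


def read_corridors(path: str | Path) -> list[Corridor]:
    geoms, props = read_geojson(path)
    return [Corridor(corridor_id=p.get("id", f"corridor_{i}"), centerline=g) for i, (g, p) in enumerate(zip(geoms, props))]


def segmentize(line: LineString) -> list[LineString]:
    """Split a polyline into its individual straight segments."""
    coords = np.asarray(line.coords)
    return [LineString(coords[i : i + 2]) for i in range(len(coords) - 1)]
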