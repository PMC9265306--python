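"""Buffer-based spatial units around survey clusters.

The analysis row is the circular buffer around a cluster's published point:
2 km radius for urban clusters, 5 km for rural ones (the DHS displacement
blur).  Units are kept only if their coordinates are valid and their buffer
contains at least one urban land-cover pixel; included units are then
stratified into an urban subset by comparing each unit's urbanised fraction
with the mean over included units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Point, mapping, shape

from .raster import Raster
from .synth import Cluster, urban_mask

__all__ = ["SpatialUnit", "build_buffers", "apply_inclusion", "stratify_urban",
           "write_units_geojson", "read_units_geojson"]

BUFFER_QUAD_SEGS = 32  # 128-segment circle; area error ~0.04% < 0.1%


@dataclass
class SpatialUnit:
    cluster: Cluster
    buffer_radius_m: float
    polygon: shapely.Polygon
    urban_pixel_count: int = 0
    urbanised_fraction: float = 0.0
    included: bool = False
    in_urban_subset: bool = False

    @property
    def cluster_id(self) -> int:
        return self.cluster.cluster_id


def build_buffers(clusters: list[Cluster],
                  radii_m: tuple[float, float] = (2000.0, 5000.0)) -> list[SpatialUnit]:
    """One unit per cluster: a 64-segment circle around the reported point.

    ``radii_m`` is (urban, rural).
    """
    if not clusters:
        raise ValueError("no clusters given")
    units = []
    for cl in clusters:
        r = radii_m[0] if cl.is_urban else radii_m[1]
        poly = Point(cl.reported_point).buffer(r, quad_segs=BUFFER_QUAD_SEGS)
        units.append(SpatialUnit(cluster=cl, buffer_radius_m=r, polygon=poly))
    return units


def pixels_in_polygon(raster: Raster, polygon: shapely.Polygon) -> np.ndarray:
    """Boolean mask of raster cells whose *centre* lies inside the polygon."""
    xmin, ymin, xmax, ymax = polygon.bounds
    X, Y = raster.cell_centers()
    out = np.zeros(raster.shape, dtype=bool)
    cand = (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
    if not cand.any():
        return out
    out[cand] = shapely.contains_xy(polygon, X[cand], Y[cand])
    return out


def apply_inclusion(units: list[SpatialUnit], landcover: Raster) -> list[SpatialUnit]:
    """Set inclusion flags: valid coordinates AND >= 1 urban pixel in buffer.

    Also populates urban_pixel_count and urbanised_fraction (urban pixel
    area over polygonised buffer area) for every unit.
    """
    um = urban_mask(landcover)
    cell_area = landcover.cell_size ** 2
    for u in units:
        inside = pixels_in_polygon(landcover, u.polygon)
        u.urban_pixel_count = int((inside & um).sum())
        u.urbanised_fraction = min(1.0, u.urban_pixel_count * cell_area / u.polygon.area)
        u.included = bool(u.cluster.valid_coords and u.urban_pixel_count >= 1)
    return units


def stratify_urban(units: list[SpatialUnit]) -> list[SpatialUnit]:
    """Mark the urban subset: urbanised fraction strictly above the mean
    urbanised fraction of included units."""
    included = [u for u in units if u.included]
    if len(included) < 2:
        raise ValueError("need at least 2 included units to stratify")
    mean_frac = float(np.mean([u.urbanised_fraction for u in included]))
    any_above = False
    for u in units:
        u.in_urban_subset = bool(u.included and u.urbanised_fraction > mean_frac)
        any_above = any_above or u.in_urban_subset
    if not any_above:
        warnings.warn("all urbanised fractions equal: urban subset is empty")
    return units


# -- IO ---------------------------------------------------------------------


def write_units_geojson(units: list[SpatialUnit], path: str | Path) -> None:
    feats = []
    for u in units:
        feats.append({
            "type": "Feature",
            "geometry": mapping(u.polygon),
            "properties": {
                "cluster_id": u.cluster_id,
                "is_urban": u.cluster.is_urban,
                "dhs_weight": u.cluster.dhs_weight,
                "valid_coords": u.cluster.valid_coords,
                "buffer_radius_m": u.buffer_radius_m,
                "urban_pixel_count": u.urban_pixel_count,
                "urbanised_fraction": u.urbanised_fraction,
                "included": u.included,
                "in_urban_subset": u.in_urban_subset,
            },
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_units_geojson(path: str | Path) -> list[SpatialUnit]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        p = feat["properties"]
        poly = shape(feat["geometry"])
        cl = Cluster(
            cluster_id=int(p["cluster_id"]),
            reported_point=(poly.centroid.x, poly.centroid.y),
            is_urban=bool(p["is_urban"]),
            dhs_weight=float(p["dhs_weight"]),
            valid_coords=bool(p["valid_coords"]),
        )
        out.append(SpatialUnit(
            cluster=cl, buffer_radius_m=float(p["buffer_radius_m"]), polygon=poly,
            urban_pixel_count=int(p["urban_pixel_count"]),
            urbanised_fraction=float(p["urbanised_fraction"]),
            included=bool(p["included"]),
            in_urban_subset=bool(p["in_urban_subset"]),
        ))
    return out
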