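"""Per-unit landscape metrics on categorical rasters, plus road indicators.

A *patch* is a maximal connected set of same-class cells inside a unit
(8-connectivity by default, the convention of raster landscape-metric
tools).  For every class the unit battery holds the class proportion, total
edge length, and a patch-shape summary; urban precarity classes from the
cross-classification are treated as classes of their own, and the retained
exposure — the dense-precarious patch area over buffer area — is computed
alongside road density and linearity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .raster import Raster
from .synth import RoadNetwork, edge_length, edge_chord
from .units import SpatialUnit, pixels_in_polygon
from .urban import UrbanClassification, CODE_PRECARIOUS, CODE_DENSE_PRECARIOUS

__all__ = ["Patch", "delineate_patches", "class_proportion", "total_edge",
           "shape_index", "min_perimeter", "unit_shape_metric",
           "class_area_over_buffer", "road_density", "road_linearity",
           "compute_unit_metrics"]

_STRUCTURES = {4: ndimage.generate_binary_structure(2, 1),
               8: ndimage.generate_binary_structure(2, 2)}


@dataclass
class Patch:
    class_code: float
    cells: np.ndarray  # (n, 2) row/col indices
    area_cells: int
    perimeter_edges: int
    cell_size: float

    @property
    def area_m2(self) -> float:
        return self.area_cells * self.cell_size ** 2

    @property
    def perimeter_m(self) -> float:
        return self.perimeter_edges * self.cell_size


def _patch_perimeter(member: np.ndarray, region: np.ndarray,
                     include_boundary: bool) -> int:
    """Count exposed 4-faces of ``member`` cells.

    A face is exposed when the 4-neighbour is not part of the same patch;
    faces that leave the unit ``region`` (or the grid) count only when
    ``include_boundary`` is true.
    """
    edges = 0
    padded = np.pad(member, 1, constant_values=False)
    reg = np.pad(region, 1, constant_values=False)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = np.roll(np.roll(padded, dr, axis=0), dc, axis=1)
        nb_reg = np.roll(np.roll(reg, dr, axis=0), dc, axis=1)
        exposed = padded & ~nb
        if not include_boundary:
            exposed &= nb_reg  # only faces toward cells still inside the unit
        edges += int(exposed.sum())
    return edges


def delineate_patches(class_values: np.ndarray, unit_mask: np.ndarray,
                      class_code: float, connectivity: int = 8,
                      cell_size: float = 1.0,
                      include_boundary: bool = True) -> list[Patch]:
    """Connected components of ``class_code`` cells within the unit mask."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    member = (class_values == class_code) & unit_mask
    labels, n = ndimage.label(member, structure=_STRUCTURES[connectivity])
    patches = []
    for lab in range(1, n + 1):
        m = labels == lab
        cells = np.argwhere(m)
        patches.append(Patch(
            class_code=class_code, cells=cells, area_cells=int(m.sum()),
            perimeter_edges=_patch_perimeter(m, unit_mask, include_boundary),
            cell_size=cell_size,
        ))
    return patches


def class_proportion(class_values: np.ndarray, unit_mask: np.ndarray,
                     class_code: float) -> float:
    total = int(unit_mask.sum())
    if total == 0:
        raise ValueError("unit has no cells")
    return float(((class_values == class_code) & unit_mask).sum() / total)


def total_edge(patches: list[Patch], cell_size: float | None = None) -> float:
    """Summed exposed-face length (metres) over a class's patches."""
    if not patches:
        return 0.0
    cs = cell_size if cell_size is not None else patches[0].cell_size
    return float(sum(p.perimeter_edges for p in patches) * cs)


def min_perimeter(area_cells: int) -> int:
    """Perimeter (in cell edges) of the most compact raster patch of given area."""
    n = int(math.isqrt(area_cells))
    if area_cells == n * n:
        return 4 * n
    if area_cells <= n * (n + 1):
        return 4 * n + 2
    return 4 * n + 4


def shape_index(patch: Patch) -> float:
    """Patch perimeter over the minimum perimeter at equal area; 1 = compact."""
    return patch.perimeter_edges / min_perimeter(patch.area_cells)


def unit_shape_metric(patches: list[Patch], variant: str = "per_patch") -> float:
    """Patch-shape summary for a class within a unit.

    ``per_patch``: sum(area_i * shape_i) / N_patches, areas in m2 (the
    study's tabulated formula).  ``area_weighted``: the standard
    area-weighted mean shape index, sum(area_i * shape_i) / sum(area_i).
    """
    if not patches:
        raise ValueError("no patches: shape metric undefined")
    num = sum(p.area_m2 * shape_index(p) for p in patches)
    if variant == "per_patch":
        return float(num / len(patches))
    if variant == "area_weighted":
        return float(num / sum(p.area_m2 for p in patches))
    raise ValueError("variant must be 'per_patch' or 'area_weighted'")


def class_area_over_buffer(patches: list[Patch], buffer_area_m2: float) -> float:
    if not buffer_area_m2 > 0:
        raise ValueError("buffer area must be positive")
    return float(sum(p.area_m2 for p in patches) / buffer_area_m2)


def road_linearity(edge: np.ndarray) -> float:
    """Polyline length over the straight distance between its end vertices."""
    chord = edge_chord(edge)
    if chord == 0:
        raise ValueError("closed loop: linearity undefined")
    return edge_length(edge) / chord


def clip_roads(roads: RoadNetwork, polygon: shapely.Polygon) -> list[shapely.LineString]:
    clipped = []
    for e in roads.edges:
        geom = shapely.LineString(e)
        inter = geom.intersection(polygon)
        if inter.is_empty:
            continue
        if inter.geom_type == "LineString":
            clipped.append(inter)
        elif inter.geom_type == "MultiLineString":
            clipped.extend(inter.geoms)
    return clipped


def road_density(roads_clipped: list[shapely.LineString], builtup_area_ha: float) -> float:
    """Total clipped road length (km) per hectare of built-up area."""
    if not builtup_area_ha > 0:
        raise ValueError("built-up area must be positive")
    total_km = sum(g.length for g in roads_clipped) / 1000.0
    return float(total_km / builtup_area_ha)


# ---------------------------------------------------------------------------
# per-unit battery


def _crop(raster_values: np.ndarray, raster: Raster, polygon: shapely.Polygon):
    """Row/col slices of the raster covering the polygon's bounding box."""
    xmin, ymin, xmax, ymax = polygon.bounds
    x0, y0 = raster.origin
    cs = raster.cell_size
    nrows, ncols = raster.shape
    c0 = max(0, int(math.floor((xmin - x0) / cs)))
    c1 = min(ncols, int(math.ceil((xmax - x0) / cs)))
    rtop = max(0, nrows - int(math.ceil((ymax - y0) / cs)))
    rbot = min(nrows, nrows - int(math.floor((ymin - y0) / cs)))
    return slice(rtop, rbot), slice(c0, c1)


def compute_unit_metrics(units: list[SpatialUnit], landcover: Raster,
                         classification: UrbanClassification | None = None,
                         roads: RoadNetwork | None = None,
                         connectivity: int = 8,
                         include_boundary: bool = True,
                         shape_variant: str = "per_patch",
                         linearity_weighted: bool = False) -> pd.DataFrame:
    """Compute the full independent-variable battery for each included unit.

    Returns a wide DataFrame indexed by cluster_id with, per land-cover
    class c: ``prop_{c}``, ``edge_{c}``, ``shape_{c}`` (0 when the class is
    absent); the urban precarity indicators ``pct_dense_urban``,
    ``pct_precarious_urban``, ``precarious_area_frac``,
    ``dense_precarious_area_frac``; and ``road_km_per_ha``,
    ``road_linearity`` when a road network is given.
    """
    legend = landcover.legend or {}
    class_codes = {float(code): name for code, name in legend.items()}
    cs = landcover.cell_size
    rows = {}
    lin_cache = None
    if roads is not None:
        lin_cache = []
        for e in roads.edges:
            try:
                lin_cache.append((shapely.LineString(e), road_linearity(e),
                                  edge_length(e)))
            except ValueError:
                warnings.warn("closed-loop road edge excluded from linearity")
    for u in units:
        if not u.included:
            continue
        rs, cls_ = _crop(landcover.values, landcover, u.polygon)
        sub = Raster(landcover.values[rs, cls_], cs,
                     (landcover.origin[0] + cls_.start * cs,
                      landcover.origin[1] + (landcover.shape[0] - rs.stop) * cs),
                     nodata=landcover.nodata)
        umask = pixels_in_polygon(sub, u.polygon) & (sub.values != landcover.nodata)
        if not umask.any():
            continue
        row: dict[str, float] = {}
        for code, name in class_codes.items():
            patches = delineate_patches(sub.values, umask, code, connectivity,
                                        cs, include_boundary)
            row[f"prop_{name}"] = class_proportion(sub.values, umask, code)
            row[f"edge_{name}"] = total_edge(patches, cs)
            row[f"shape_{name}"] = (unit_shape_metric(patches, shape_variant)
                                    if patches else 0.0)
        if classification is not None:
            cgrid = classification.class_grid.values[rs, cls_]
            urb = classification.urban[rs, cls_] & umask
            n_urb = int(urb.sum())
            dens = classification.density300.values[rs, cls_]
            if n_urb > 0:
                row["pct_dense_urban"] = float(
                    (dens[urb] > classification.density_median).sum() / n_urb)
                row["pct_precarious_urban"] = float(
                    (cgrid[urb] >= CODE_PRECARIOUS).sum() / n_urb)
            else:
                row["pct_dense_urban"] = 0.0
                row["pct_precarious_urban"] = 0.0
            for code, col in ((CODE_PRECARIOUS, "precarious_area_frac"),
                              (CODE_DENSE_PRECARIOUS, "dense_precarious_area_frac")):
                if code == CODE_PRECARIOUS:
                    member_area = float(((cgrid >= code) & umask).sum() * cs * cs)
                else:
                    member_area = float(((cgrid == code) & umask).sum() * cs * cs)
                row[col] = member_area / u.polygon.area
        if roads is not None and lin_cache is not None:
            clipped = []
            lins = []
            lens = []
            for geom, lin, ln in lin_cache:
                inter = geom.intersection(u.polygon)
                if inter.is_empty:
                    continue
                clipped.append(inter)
                lins.append(lin)
                lens.append(ln)
            builtup_ha = u.urban_pixel_count * cs * cs / 1e4
            segments = [seg for g in clipped
                        for seg in (g.geoms if hasattr(g, "geoms") else [g])
                        if seg.geom_type == "LineString"]
            row["road_km_per_ha"] = (road_density(segments, builtup_ha)
                                     if builtup_ha > 0 else 0.0)
            if lins:
                if linearity_weighted:
                    row["road_linearity"] = float(np.average(lins, weights=lens))
                else:
                    row["road_linearity"] = float(np.mean(lins))
            else:
                row["road_linearity"] = 0.0
        rows[u.cluster_id] = row
    df = pd.DataFrame(rows).T
    df.index.name = "cluster_id"
    return df
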