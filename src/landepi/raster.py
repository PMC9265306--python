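"""Lightweight georeferenced raster container with plain-text (ASCII grid) IO.

The analysis works in a planar metric coordinate system: a raster is a
rectangular array of square cells of side ``cell_size`` metres whose
lower-left corner sits at ``origin``.  Row 0 of ``values`` is the *top*
(northernmost) row, matching the ESRI ASCII grid convention used for IO.

Three grid resolutions coexist in the analysis (land cover at 300 m, night
lights at 500 m, population at 100 m); :func:`resample` moves layers onto a
common analysis grid with exact axis-aligned area weighting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Raster", "resample"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band georeferenced grid.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; category codes for categorical layers, real
        intensities otherwise.  Row 0 is the top row.
    cell_size : float
        Cell edge length in metres (> 0).
    origin : (float, float)
        Planar coordinates of the lower-left corner of the grid, metres.
    nodata : float
        Sentinel for missing cells; must never be a legal category code.
    kind : str
        One of ``landcover | lights | population | class | generic``.
    legend : dict or None
        For categorical rasters, maps integer code -> class name.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA
    kind: str = "generic"
    legend: dict | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in metres."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def x_centers(self) -> np.ndarray:
        ncols = self.shape[1]
        return self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Y coordinate of each row centre, row 0 first (top row)."""
        nrows = self.shape[0]
        return self.origin[1] + (nrows - np.arange(nrows) - 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrids (X, Y) of cell-centre coordinates, same shape as values."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where data is valid."""
        return self.values != self.nodata

    def copy(self, **overrides) -> "Raster":
        kw = dict(
            values=self.values.copy(),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata=self.nodata,
            kind=self.kind,
            legend=dict(self.legend) if self.legend else None,
        )
        kw.update(overrides)
        return Raster(**kw)

    def blank_like(self, fill: float = 0.0) -> "Raster":
        return self.copy(values=np.full(self.shape, fill, dtype=float))

    # -- IO -----------------------------------------------------------------

    def write_ascii(self, path: str | Path) -> None:
        """Write as an ESRI ASCII grid plus a JSON sidecar with metadata."""
        path = Path(path)
        nrows, ncols = self.shape
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.origin[0]:.6f}\n"
            f"yllcorner {self.origin[1]:.6f}\n"
            f"cellsize {self.cell_size:.6f}\n"
            f"NODATA_value {self.nodata:.6f}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, self.values, fmt="%.10g")
        sidecar = {"kind": self.kind, "legend": self.legend}
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_ascii(cls, path: str | Path) -> "Raster":
        path = Path(path)
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        kind, legend = "generic", None
        sidecar = Path(str(path) + ".json")
        if sidecar.exists():
            side = json.loads(sidecar.read_text())
            kind = side.get("kind", "generic")
            legend = side.get("legend")
            if legend is not None:
                legend = {int(k): v for k, v in legend.items()}
        return cls(
            values=values,
            cell_size=meta["cellsize"],
            origin=(meta["xllcorner"], meta["yllcorner"]),
            nodata=meta["nodata_value"],
            kind=kind,
            legend=legend,
        )


# -- resampling -------------------------------------------------------------


def _overlap_matrix(n_out: int, o_out: float, s_out: float,
                    n_in: int, o_in: float, s_in: float) -> np.ndarray:
    """1-D overlap lengths between output and input cell intervals.

    Returns a dense (n_out, n_in) matrix M with M[i, j] = length of the
    intersection of output interval i and input interval j, in metres.
    Axis-aligned 2-D overlap areas factorise into products of these.
    """
    lo_out = o_out + np.arange(n_out) * s_out
    hi_out = lo_out + s_out
    lo_in = o_in + np.arange(n_in) * s_in
    hi_in = lo_in + s_in
    lo = np.maximum(lo_out[:, None], lo_in[None, :])
    hi = np.minimum(hi_out[:, None], hi_in[None, :])
    return np.clip(hi - lo, 0.0, None)


def resample(src: Raster, like: Raster, method: str = "area_weighted_mean") -> Raster:
    """Resample ``src`` onto the grid of ``like``.

    method:
        ``area_weighted_mean`` — intensive quantities (densities,
        intensities); output bounded by the input range.
        ``sum`` — extensive quantities (counts); conserves the raster
        total over the overlapping region.
        ``nearest`` — categorical layers; value of the input cell containing
        each output cell centre.
    """
    if method not in {"area_weighted_mean", "sum", "nearest"}:
        raise ValueError(f"unknown resampling method: {method!r}")
    sx0, sy0, sx1, sy1 = src.extent
    tx0, ty0, tx1, ty1 = like.extent
    if sx1 <= tx0 or tx1 <= sx0 or sy1 <= ty0 or ty1 <= sy0:
        raise ValueError("source and target extents do not overlap")

    nrows_t, ncols_t = like.shape
    nrows_s, ncols_s = src.shape

    if method == "nearest":
        xc = like.x_centers()
        yc = like.y_centers()
        col = np.floor((xc - src.origin[0]) / src.cell_size).astype(int)
        row_from_bottom = np.floor((yc - src.origin[1]) / src.cell_size).astype(int)
        row = nrows_s - 1 - row_from_bottom
        out = np.full(like.shape, src.nodata, dtype=src.values.dtype)
        ok_c = (col >= 0) & (col < ncols_s)
        ok_r = (row >= 0) & (row < nrows_s)
        rr, cc = np.meshgrid(row, col, indexing="ij")
        inside = ok_r[:, None] & ok_c[None, :]
        out[inside] = src.values[rr[inside], cc[inside]]
        return Raster(out, like.cell_size, like.origin, nodata=src.nodata,
                      kind=src.kind, legend=src.legend)

    # x-axis overlaps (columns) and y-axis overlaps (rows, top-first order)
    mx = _overlap_matrix(ncols_t, like.origin[0], like.cell_size,
                         ncols_s, src.origin[0], src.cell_size)
    # build along y from the bottom, then flip both axes to top-first rows
    my_bottom = _overlap_matrix(nrows_t, like.origin[1], like.cell_size,
                                nrows_s, src.origin[1], src.cell_size)
    my = my_bottom[::-1, ::-1]  # reindex both grids from bottom-first to top-first rows

    vals = np.where(src.mask, src.values.astype(float), 0.0)
    wts = src.mask.astype(float)

    if method == "sum":
        # share of each src cell's value handed to each target cell
        frac_y = my / src.cell_size
        frac_x = mx / src.cell_size
        out = frac_y @ vals @ frac_x.T
        wsum = frac_y @ wts @ frac_x.T
        out = np.where(wsum > 0, out, src.nodata)
        return Raster(out, like.cell_size, like.origin, nodata=src.nodata,
                      kind=src.kind)

    # area-weighted mean
    num = my @ (vals * 1.0) @ mx.T
    den = my @ wts @ mx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), src.nodata)
    return Raster(out, like.cell_size, like.origin, nodata=src.nodata,
                  kind=src.kind)
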