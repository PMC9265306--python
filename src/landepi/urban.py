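"""Quantile cross-classification of urban pixels into precarity classes.

The construct: night-light intensity proxies the presence of urban
infrastructure.  If infrastructure keeps pace with settlement, illumination
tracks demographic density; an urban pixel whose density sits in a *higher*
quantile than its illumination is read as infrastructure-deficient —
"precarious".  The retained exposure class, "dense, precarious", is the
subset with density in the top decile and illumination above the median but
below the top decile.

Quantiles are ranked over the urban pixels of the whole study area (one
shared series), so labels are comparable across spatial units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import Raster, resample
from .synth import urban_mask

__all__ = ["quantile_rank", "classify_precarious", "classify_dense_precarious",
           "UrbanClassification", "classify_urban", "CODE_REGULAR",
           "CODE_PRECARIOUS", "CODE_DENSE_PRECARIOUS"]

CODE_REGULAR = 1
CODE_PRECARIOUS = 2
CODE_DENSE_PRECARIOUS = 3  # subset of precarious

CLASS_LEGEND = {CODE_REGULAR: "urban_regular",
                CODE_PRECARIOUS: "urban_precarious",
                CODE_DENSE_PRECARIOUS: "urban_dense_precarious"}


def quantile_rank(values: np.ndarray, n_quantiles: int) -> np.ndarray:
    """Empirical-CDF quantile index in 1..n_quantiles for each value.

    A value with r other values strictly below it (out of N) gets index
    floor(r * n / N) + 1: bins are balanced up to ties, and tied values all
    share the index of their lowest member (a tie never raises a rank).
    """
    values = np.asarray(values, dtype=float)
    if n_quantiles < 2:
        raise ValueError("need n_quantiles >= 2")
    n = values.size
    if n < n_quantiles:
        raise ValueError("need at least n_quantiles values")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    # r[i] = count of values strictly less than values[i]
    strictly_less = np.searchsorted(sorted_vals, values, side="left")
    ranks = (strictly_less * n_quantiles) // n + 1
    ranks = np.minimum(ranks, n_quantiles).astype(int)
    if np.all(values == values[0]):
        warnings.warn("all values identical: every pixel in quantile 1")
    return ranks


def classify_precarious(density_q: np.ndarray, light_q: np.ndarray) -> np.ndarray:
    """Precarious iff the density quantile strictly exceeds the light quantile."""
    density_q = np.asarray(density_q)
    light_q = np.asarray(light_q)
    if density_q.shape != light_q.shape:
        raise ValueError("quantile grids have mismatched shapes")
    return density_q > light_q


def classify_dense_precarious(density_q: np.ndarray, light_q: np.ndarray,
                              n_quantiles: int = 10) -> np.ndarray:
    """Dense precarious: density in the top decile, light above the median
    but below the top decile (deciles are the canonical definition)."""
    if n_quantiles != 10:
        raise ValueError("the canonical dense-precarious rule is defined on deciles")
    density_q = np.asarray(density_q)
    light_q = np.asarray(light_q)
    if density_q.shape != light_q.shape:
        raise ValueError("quantile grids have mismatched shapes")
    return (density_q == 10) & (light_q > 5) & (light_q < 10)


@dataclass
class UrbanClassification:
    """Per-pixel precarity labels plus the series used to build them.

    class_grid: raster of codes (CLASS_LEGEND) over urban pixels, nodata
    elsewhere.  density300/lights300: the layers resampled to the analysis
    grid.  density_median: median density over the urban series (for the
    "% dense urban" metric).
    """

    class_grid: Raster
    density_q: np.ndarray
    light_q: np.ndarray
    urban: np.ndarray  # boolean mask on the analysis grid
    n_quantiles: int
    density300: Raster
    lights300: Raster
    density_median: float

    @property
    def precarious(self) -> np.ndarray:
        return self.class_grid.values >= CODE_PRECARIOUS

    @property
    def dense_precarious(self) -> np.ndarray:
        return self.class_grid.values == CODE_DENSE_PRECARIOUS


def classify_urban(landcover: Raster, lights: Raster, population: Raster,
                   n_quantiles: int = 10) -> UrbanClassification:
    """Run the full cross-classification on the land-cover analysis grid.

    Lights and population are resampled to the 300 m land-cover grid by
    area-weighted mean (both enter as intensive quantities for ranking),
    ranked into quantiles over urban pixels, and labelled.
    """
    um = urban_mask(landcover)
    if um.sum() < n_quantiles:
        raise ValueError("fewer urban pixels than quantiles")
    dens = resample(population, landcover, method="area_weighted_mean")
    ligh = resample(lights, landcover, method="area_weighted_mean")

    dq = np.zeros(landcover.shape, dtype=int)
    lq = np.zeros(landcover.shape, dtype=int)
    dq[um] = quantile_rank(dens.values[um], n_quantiles)
    lq[um] = quantile_rank(ligh.values[um], n_quantiles)

    codes = np.full(landcover.shape, landcover.nodata)
    codes[um] = CODE_REGULAR
    prec = np.zeros(landcover.shape, dtype=bool)
    prec[um] = classify_precarious(dq[um], lq[um])
    codes[prec] = CODE_PRECARIOUS
    if n_quantiles == 10:
        dense = np.zeros(landcover.shape, dtype=bool)
        dense[um] = classify_dense_precarious(dq[um], lq[um], n_quantiles)
        codes[dense & prec] = CODE_DENSE_PRECARIOUS

    grid = Raster(codes, landcover.cell_size, landcover.origin,
                  nodata=landcover.nodata, kind="class", legend=dict(CLASS_LEGEND))
    return UrbanClassification(
        class_grid=grid, density_q=dq, light_q=lq, urban=um,
        n_quantiles=n_quantiles, density300=dens, lights300=ligh,
        density_median=float(np.median(dens.values[um])),
    )
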