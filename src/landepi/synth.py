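"""Synthetic study-world generators with known ground truth.

Every input layer of the analysis — categorical land cover (300 m), night
lights (500 m), population density (100 m), roads, survey clusters with
DHS-style coordinate displacement, and household/woman survey tables — is
generated from seeded random fields so that each downstream stage can be
tested against a planted truth.

Spatial autocorrelation is induced by Gaussian smoothing of white noise.
The key planted structure is an *infrastructure deficit* field D(x) in
[0, 1]: night lights follow ``gain * density * (1 - D) + noise``, so a
deficit rectangle decouples illumination from density exactly the way the
precarity classification is designed to detect.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import Raster, resample

__all__ = [
    "RoadNetwork", "Cluster", "SurveyTable", "TruthRecord",
    "generate_landcover", "generate_population", "generate_nightlights",
    "make_deficit_rectangle", "generate_roads", "generate_clusters",
    "generate_survey", "write_clusters_geojson", "read_clusters_geojson",
    "write_roads_geojson", "read_roads_geojson",
]

URBAN = "urban"


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RoadNetwork:
    """Polyline road edges in planar metres."""

    edges: list[np.ndarray]  # each (n_vertices, 2), n_vertices >= 2
    edge_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.edge_ids:
            self.edge_ids = list(range(len(self.edges)))
        for e in self.edges:
            e = np.asarray(e, dtype=float)
            if e.shape[0] < 2:
                raise ValueError("polyline needs at least 2 vertices")
            if edge_length(e) == 0:
                raise ValueError("zero-length polyline")

    def total_length(self) -> float:
        return float(sum(edge_length(e) for e in self.edges))


def edge_length(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.sum(np.hypot(np.diff(v[:, 0]), np.diff(v[:, 1]))))


def edge_chord(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    return float(np.hypot(*(v[-1] - v[0])))


@dataclass
class Cluster:
    """A survey cluster: one published (displaced) point for many households."""

    cluster_id: int
    reported_point: tuple[float, float]
    is_urban: bool
    dhs_weight: float
    valid_coords: bool = True
    true_point: tuple[float, float] | None = None  # synthetic ground truth

    def __post_init__(self) -> None:
        if not self.dhs_weight > 0:
            raise ValueError("dhs_weight must be positive")


@dataclass
class SurveyTable:
    """Household and woman (15-49) records, linked to clusters by id.

    households columns: cluster_id, household_id, n_members, n_under5,
    n_diarrhoea_cases, basic_water, basic_sanitation.
    women columns: cluster_id, woman_id, no_education.
    """

    households: pd.DataFrame
    women: pd.DataFrame

    def validate(self) -> None:
        hh = self.households
        if ((hh.n_diarrhoea_cases < 0) | (hh.n_diarrhoea_cases > hh.n_under5)).any():
            raise ValueError("need 0 <= cases <= under-5 count")
        if ((hh.n_under5 < 0) | (hh.n_under5 > hh.n_members)).any():
            raise ValueError("need 0 <= under-5 count <= household members")

    def write_csv(self, households_path: str | Path, women_path: str | Path) -> None:
        self.households.to_csv(households_path, index=False)
        self.women.to_csv(women_path, index=False)

    @classmethod
    def read_csv(cls, households_path: str | Path, women_path: str | Path) -> "SurveyTable":
        return cls(pd.read_csv(households_path), pd.read_csv(women_path))


@dataclass
class TruthRecord:
    """Generator parameters sufficient to regenerate a synthetic dataset.

    ``beta`` maps feature-table column names (on the min/max-scaled design)
    to linear-model coefficients for the latent cluster prevalence.  At most
    one of ``rho`` (lag) and ``lam`` (error) may be non-zero.
    """

    alpha: float = 0.43
    beta: dict[str, float] = field(default_factory=lambda: {
        "pct_basic_water": 0.0,
        "pct_basic_sanitation": -0.19,
        "pct_women_no_education": -0.14,
        "dense_precarious_area_frac": 0.26,
    })
    rho: float = 0.0
    lam: float = 0.0
    noise_sd: float = 0.15
    link: str = "identity"  # identity | logistic
    households_per_cluster: float = 27.0
    member_mean: float = 4.0  # members ~ 1 + Poisson(member_mean)
    under5_rate: float = 0.18
    deficit_amplitude: float = 0.6
    deficit_area_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rho != 0.0 and self.lam != 0.0:
            raise ValueError("specify at most one of rho (lag) and lam (error)")
        if self.link not in {"identity", "logistic"}:
            raise ValueError("link must be 'identity' or 'logistic'")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# random-field helper


def _smoothed_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Standardised (mean 0, sd 1) Gaussian-smoothed white-noise field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


# ---------------------------------------------------------------------------
# raster generators


def generate_landcover(extent_m: float, cell_size: float, class_spec: dict[str, float],
                       seed: int, smooth_sigma: float = 4.0,
                       origin: tuple[float, float] = (0.0, 0.0)) -> Raster:
    """Categorical land-cover raster with target per-class fractions.

    Classes are carved out of a single smoothed random field by quantile
    slices, so each class (in particular ``urban``) forms contiguous blobs.
    The ``urban`` class occupies the top slice of the field.  Codes are
    assigned 1..K in the order of ``class_spec`` with urban forced last.
    """
    total = sum(class_spec.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class fractions must sum to 1, got {total}")
    if any(v < 0 for v in class_spec.values()):
        raise ValueError("class fractions must be non-negative")
    n = int(round(extent_m / cell_size))
    if abs(n * cell_size - extent_m) > 1e-6:
        raise ValueError("extent must be divisible by cell_size")

    names = [c for c in class_spec if c != URBAN]
    if URBAN in class_spec:
        names.append(URBAN)  # urban takes the highest field values
    rng = np.random.default_rng(seed)
    f = _smoothed_field((n, n), smooth_sigma, rng)

    order = np.argsort(f, axis=None, kind="stable")
    codes = np.empty(n * n, dtype=float)
    legend: dict[int, str] = {}
    start = 0
    cum = 0.0
    for i, name in enumerate(names):
        cum += class_spec[name]
        stop = n * n if i == len(names) - 1 else int(round(cum * n * n))
        codes[order[start:stop]] = i + 1
        legend[i + 1] = name
        start = stop
    values = codes.reshape(n, n)
    return Raster(values, cell_size, origin, kind="landcover", legend=legend)


def urban_code(landcover: Raster) -> int:
    if not landcover.legend:
        raise ValueError("landcover raster has no legend")
    for code, name in landcover.legend.items():
        if name == URBAN:
            return int(code)
    raise ValueError("landcover has no 'urban' class")


def urban_mask(landcover: Raster) -> np.ndarray:
    return landcover.values == urban_code(landcover)


def generate_population(landcover: Raster, urban_mean: float, rural_mean: float,
                        seed: int, cell_size: float = 100.0,
                        noise_sigma_log: float = 0.5,
                        smooth_sigma: float = 6.0,
                        primacy: float = 1.0) -> Raster:
    """Population-density raster (people per cell) at ``cell_size`` metres.

    Mean density is ``urban_mean`` on urban-covered cells and ``rural_mean``
    elsewhere; multiplicative log-normal spatial noise (smoothed, with the
    lognormal mean correction) preserves those stratum means in expectation.

    ``primacy`` emulates urban primacy — the concentration of demographic
    growth in the largest agglomerations: urban density is additionally
    scaled by (local urban share / its urban-wide mean) ** primacy, where
    the local urban share is a Gaussian-smoothed urban indicator.  With
    primacy 0 all urban blobs share the same mean density; with primacy 1
    the cores of the largest blobs are the densest.  The urban stratum mean
    is renormalised so ``urban_mean`` still holds.
    """
    if urban_mean < 0 or rural_mean < 0:
        raise ValueError("mean densities must be non-negative")
    x0, y0, x1, y1 = landcover.extent
    n_rows = int(round((y1 - y0) / cell_size))
    n_cols = int(round((x1 - x0) / cell_size))
    template = Raster(np.zeros((n_rows, n_cols)), cell_size, (x0, y0),
                      nodata=landcover.nodata, kind="population")
    lc_fine = resample(landcover, template, method="nearest")
    if not lc_fine.mask.any():
        return template.copy(values=np.full((n_rows, n_cols), landcover.nodata))

    rng = np.random.default_rng(seed)
    g = _smoothed_field((n_rows, n_cols), smooth_sigma, rng)
    noise = np.exp(noise_sigma_log * g - 0.5 * noise_sigma_log ** 2)
    is_urb = lc_fine.values == urban_code(landcover)
    base = np.where(is_urb, urban_mean, rural_mean).astype(float)
    if primacy > 0 and is_urb.any():
        # smoothed urban indicator ~ local agglomeration size
        local = gaussian_filter(is_urb.astype(float),
                                sigma=3.0 * smooth_sigma, mode="reflect")
        rel = np.clip(local / local[is_urb].mean(), 1e-6, None) ** primacy
        rel = rel / rel[is_urb].mean()  # keep the urban stratum mean
        base[is_urb] *= rel[is_urb]
    values = np.where(lc_fine.mask, base * noise, landcover.nodata)
    return Raster(values, cell_size, (x0, y0), nodata=landcover.nodata,
                  kind="population")


def make_deficit_rectangle(landcover: Raster, population: Raster,
                           area_fraction: float = 0.4,
                           amplitude: float = 0.6) -> tuple[Raster, tuple[float, float, float, float]]:
    """Plant an infrastructure-deficit rectangle over the densest urban core.

    Emulates a saturated, under-serviced settlement: a square region centred
    on the highest-density urban pixel, grown until it contains at least
    ``area_fraction`` of all urban pixels, with deficit ``amplitude`` inside
    and 0 outside.  Returns the deficit raster (on the land-cover grid) and
    the rectangle bounds (xmin, ymin, xmax, ymax).
    """
    if not 0 <= amplitude <= 1:
        raise ValueError("amplitude must be in [0, 1]")
    dens = resample(population, landcover, method="area_weighted_mean")
    um = urban_mask(landcover)
    if not um.any():
        raise ValueError("landcover has no urban pixels")
    dvals = np.where(um, dens.values, -np.inf)
    r0, c0 = np.unravel_index(np.argmax(dvals), dvals.shape)
    n_urban = int(um.sum())
    target = max(1, int(math.ceil(area_fraction * n_urban)))
    nrows, ncols = um.shape
    half = 0
    while True:
        rs = slice(max(0, r0 - half), min(nrows, r0 + half + 1))
        cs = slice(max(0, c0 - half), min(ncols, c0 + half + 1))
        if um[rs, cs].sum() >= target or (rs == slice(0, nrows) and cs == slice(0, ncols)):
            break
        half += 1
    deficit = np.zeros(um.shape)
    deficit[rs, cs] = amplitude
    return _finish_deficit(landcover, deficit, rs, cs)


def _finish_deficit(landcover: Raster, deficit: np.ndarray, rs: slice, cs: slice):
    size = landcover.cell_size
    x0g, y0g = landcover.origin
    nrows = landcover.shape[0]
    xmin = x0g + cs.start * size
    xmax = x0g + cs.stop * size
    ymax = y0g + (nrows - rs.start) * size
    ymin = y0g + (nrows - rs.stop) * size
    rast = Raster(deficit, size, landcover.origin, nodata=landcover.nodata,
                  kind="generic")
    return rast, (xmin, ymin, xmax, ymax)


def generate_nightlights(population: Raster, deficit_field: Raster, gain: float,
                         seed: int, cell_size: float = 500.0,
                         noise_sd_frac: float = 0.02) -> Raster:
    """Night-light intensity at ``cell_size`` metres.

    Expected light is ``gain * density * (1 - deficit)`` with additive
    Gaussian noise whose sd is ``noise_sd_frac`` of the mean undimmed
    signal; negative draws clip to 0 (the sensor noise floor).
    """
    dvals = deficit_field.values[deficit_field.mask]
    if dvals.size and (dvals.min() < 0 or dvals.max() > 1):
        raise ValueError("deficit field must lie in [0, 1]")
    x0, y0, x1, y1 = population.extent
    n_rows = int(round((y1 - y0) / cell_size))
    n_cols = int(round((x1 - x0) / cell_size))
    template = Raster(np.zeros((n_rows, n_cols)), cell_size, (x0, y0),
                      nodata=population.nodata, kind="lights")
    dens = resample(population, template, method="area_weighted_mean")
    defi = resample(deficit_field, template, method="area_weighted_mean")
    rng = np.random.default_rng(seed)
    signal = gain * np.where(dens.mask, dens.values, 0.0)
    dimmed = signal * (1.0 - np.where(defi.mask, defi.values, 0.0))
    floor = noise_sd_frac * (signal[dens.mask].mean() if dens.mask.any() else 1.0)
    lights = np.clip(dimmed + floor * rng.standard_normal(dimmed.shape), 0.0, None)
    lights = np.where(dens.mask, lights, population.nodata)
    return Raster(lights, cell_size, (x0, y0), nodata=population.nodata, kind="lights")


# ---------------------------------------------------------------------------
# roads


def generate_roads(landcover: Raster, linearity_target: float, seed: int,
                   n_edges: int = 200, max_span_m: float = 5000.0) -> RoadNetwork:
    """Road polylines concentrated on urban blobs.

    Each edge connects two nearby urban pixel centres; a perpendicular
    mid-point offset sets the edge's length/chord ratio exactly to
    ``linearity_target`` (1.0 gives straight segments).
    """
    if linearity_target < 1.0:
        raise ValueError("linearity_target must be >= 1")
    um = urban_mask(landcover)
    if not um.any():
        raise ValueError("landcover has no urban pixels")
    X, Y = landcover.cell_centers()
    ux, uy = X[um], Y[um]
    rng = np.random.default_rng(seed)
    edges: list[np.ndarray] = []
    pts = np.column_stack([ux, uy])
    for _ in range(n_edges):
        i = rng.integers(len(pts))
        a = pts[i]
        d = np.hypot(pts[:, 0] - a[0], pts[:, 1] - a[1])
        near = np.flatnonzero((d > 0) & (d <= max_span_m))
        if near.size == 0:
            continue
        b = pts[rng.choice(near)]
        chord = b - a
        L = np.hypot(*chord)
        if linearity_target == 1.0:
            edges.append(np.array([a, b]))
            continue
        h = 0.5 * L * math.sqrt(linearity_target ** 2 - 1.0)
        perp = np.array([-chord[1], chord[0]]) / L
        sign = 1.0 if rng.random() < 0.5 else -1.0
        mid = (a + b) / 2 + sign * h * perp
        edges.append(np.array([a, mid, b]))
    return RoadNetwork(edges)


# ---------------------------------------------------------------------------
# clusters


def generate_clusters(landcover: Raster, n_clusters: int, urban_share: float,
                      seed: int, displacement_m: tuple[float, float] = (2000.0, 5000.0),
                      invalid_fraction: float = 0.0,
                      weight_sigma_log: float = 0.3) -> list[Cluster]:
    """Survey clusters with DHS-style uniform-disc coordinate displacement.

    True points sit on pixel centres (urban clusters on urban pixels);
    reported points are displaced by radius R*sqrt(u) at a uniform angle,
    R = 2 km for urban, 5 km for rural clusters.  ``invalid_fraction``
    marks round(f*n) clusters as lacking valid coordinates.
    """
    if n_clusters < 1:
        raise ValueError("need at least one cluster")
    if not 0 <= urban_share <= 1:
        raise ValueError("urban_share must lie in [0, 1]")
    um = urban_mask(landcover)
    X, Y = landcover.cell_centers()
    rng = np.random.default_rng(seed)
    n_urban = int(round(urban_share * n_clusters))
    flags = np.zeros(n_clusters, dtype=bool)
    flags[:n_urban] = True
    rng.shuffle(flags)

    urb_pts = np.column_stack([X[um], Y[um]])
    rur_pts = np.column_stack([X[~um & landcover.mask], Y[~um & landcover.mask]])
    if n_urban > 0 and len(urb_pts) == 0:
        raise ValueError("no urban pixels to place urban clusters on")
    if n_urban < n_clusters and len(rur_pts) == 0:
        raise ValueError("no rural pixels to place rural clusters on")

    n_invalid = int(round(invalid_fraction * n_clusters))
    invalid_ids = set(rng.choice(n_clusters, size=n_invalid, replace=False).tolist())

    clusters: list[Cluster] = []
    for cid in range(n_clusters):
        is_urb = bool(flags[cid])
        pool = urb_pts if is_urb else rur_pts
        true_pt = pool[rng.integers(len(pool))]
        radius = displacement_m[0] if is_urb else displacement_m[1]
        r = radius * math.sqrt(rng.random())
        theta = 2 * math.pi * rng.random()
        rep = (float(true_pt[0] + r * math.cos(theta)),
               float(true_pt[1] + r * math.sin(theta)))
        w = float(np.exp(weight_sigma_log * rng.standard_normal()
                         - 0.5 * weight_sigma_log ** 2))
        clusters.append(Cluster(
            cluster_id=cid,
            reported_point=rep,
            is_urban=is_urb,
            dhs_weight=w,
            valid_coords=cid not in invalid_ids,
            true_point=(float(true_pt[0]), float(true_pt[1])),
        ))
    return clusters


# ---------------------------------------------------------------------------
# survey generation from a planted linear model


def latent_prevalence(X: np.ndarray, truth: TruthRecord, rng: np.random.Generator,
                      W: np.ndarray | None = None) -> np.ndarray:
    """Cluster-level latent prevalence from the planted (spatial) linear model.

    Identity link: p = clip(eta, 0.01, 0.99); logistic: p = expit(eta).
    With rho != 0 the reduced form (I - rho W)^-1 (alpha + X beta + eps) is
    used; with lam != 0 the error term is (I - lam W)^-1 eps.
    """
    n = X.shape[0]
    eps = truth.noise_sd * rng.standard_normal(n)
    beta = np.asarray(list(truth.beta.values()), dtype=float)
    xb = truth.alpha + X @ beta
    if truth.rho != 0.0:
        if W is None:
            raise ValueError("spatial lag truth needs a weights matrix")
        eta = np.linalg.solve(np.eye(n) - truth.rho * W, xb + eps)
    elif truth.lam != 0.0:
        if W is None:
            raise ValueError("spatial error truth needs a weights matrix")
        u = np.linalg.solve(np.eye(n) - truth.lam * W, eps)
        eta = xb + u
    else:
        eta = xb + eps
    if truth.link == "logistic":
        return expit(eta)
    return np.clip(eta, 0.01, 0.99)


def generate_survey(clusters: list[Cluster], covariates: pd.DataFrame,
                    truth: TruthRecord, seed: int,
                    W: np.ndarray | None = None) -> tuple[SurveyTable, pd.DataFrame]:
    """Draw household/woman records whose aggregates follow the planted model.

    ``covariates`` is indexed by cluster_id and must contain, per cluster,
    the *probabilities* for the three control variables
    (pct_basic_water, pct_basic_sanitation, pct_women_no_education) and the
    landscape columns named in ``truth.beta``.  Household flags are drawn
    from the control probabilities; the latent prevalence is then computed
    on the *realised* person-weighted shares (min/max-scaled jointly with
    the landscape columns), so the regression design downstream matches the
    generative design exactly.  Returns the survey and a per-cluster truth
    frame (realised shares, latent prevalence).
    """
    rng = np.random.default_rng(seed)
    controls = ["pct_basic_water", "pct_basic_sanitation", "pct_women_no_education"]
    for col in truth.beta:
        if col not in covariates.columns:
            raise ValueError(f"covariates missing column {col!r}")

    hh_rows = []
    woman_rows = []
    hid = 0
    wid = 0
    realised = {}
    for cl in clusters:
        cid = cl.cluster_id
        p_water = float(np.clip(covariates.loc[cid, "pct_basic_water"], 0, 1))
        p_sanit = float(np.clip(covariates.loc[cid, "pct_basic_sanitation"], 0, 1))
        p_noed = float(np.clip(covariates.loc[cid, "pct_women_no_education"], 0, 1))
        n_hh = max(1, int(rng.poisson(truth.households_per_cluster)))
        members = 1 + rng.poisson(truth.member_mean, size=n_hh)
        under5 = rng.binomial(members, truth.under5_rate)
        water = rng.random(n_hh) < p_water
        sanit = rng.random(n_hh) < p_sanit
        n_women = np.maximum(rng.binomial(members, 0.25), 0)
        for k in range(n_hh):
            hh_rows.append({
                "cluster_id": cid, "household_id": hid, "n_members": int(members[k]),
                "n_under5": int(under5[k]), "n_diarrhoea_cases": 0,
                "basic_water": int(water[k]), "basic_sanitation": int(sanit[k]),
            })
            hid += 1
            for _ in range(int(n_women[k])):
                woman_rows.append({"cluster_id": cid, "woman_id": wid,
                                   "no_education": int(rng.random() < p_noed)})
                wid += 1
        tot = members.sum()
        realised[cid] = {
            "pct_basic_water": float(members[water].sum() / tot),
            "pct_basic_sanitation": float(members[sanit].sum() / tot),
        }
    hh = pd.DataFrame(hh_rows)
    women = pd.DataFrame(woman_rows)
    noed = women.groupby("cluster_id")["no_education"].mean()
    for cid in realised:
        realised[cid]["pct_women_no_education"] = float(noed.get(cid, np.nan))
    real = pd.DataFrame(realised).T
    real.index.name = "cluster_id"

    # design matrix on the min/max-scaled realised controls + landscape columns
    cids = [cl.cluster_id for cl in clusters]
    design = pd.DataFrame(index=pd.Index(cids, name="cluster_id"))
    for col in truth.beta:
        if col in controls:
            design[col] = real.loc[cids, col].fillna(0.5).to_numpy()
        else:
            design[col] = covariates.loc[cids, col].to_numpy()
    scaled = design.copy()
    for col in scaled.columns:
        lo, hi = scaled[col].min(), scaled[col].max()
        scaled[col] = 0.0 if hi == lo else (scaled[col] - lo) / (hi - lo)

    p = latent_prevalence(scaled.to_numpy(dtype=float), truth, rng, W=W)
    p_by_cid = dict(zip(cids, p))

    cases = np.zeros(len(hh), dtype=int)
    for i, row in enumerate(hh.itertuples(index=False)):
        pc = p_by_cid[row.cluster_id]
        if row.n_under5 > 0:
            cases[i] = rng.binomial(row.n_under5, pc)
    hh["n_diarrhoea_cases"] = cases

    truth_frame = real.copy()
    truth_frame["latent_prevalence"] = [p_by_cid[c] for c in truth_frame.index]
    table = SurveyTable(hh, women)
    table.validate()
    return table, truth_frame


# ---------------------------------------------------------------------------
# GeoJSON IO (plain json + coordinate lists; planar metric CRS by convention)


def write_clusters_geojson(clusters: list[Cluster], path: str | Path) -> None:
    feats = []
    for cl in clusters:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(cl.reported_point)},
            "properties": {
                "cluster_id": cl.cluster_id,
                "is_urban": cl.is_urban,
                "dhs_weight": cl.dhs_weight,
                "valid_coords": cl.valid_coords,
                "true_point": list(cl.true_point) if cl.true_point else None,
            },
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_clusters_geojson(path: str | Path) -> list[Cluster]:
    data = json.loads(Path(path).read_text())
    out = []
    for feat in data["features"]:
        props = feat["properties"]
        tp = props.get("true_point")
        out.append(Cluster(
            cluster_id=int(props["cluster_id"]),
            reported_point=tuple(feat["geometry"]["coordinates"]),
            is_urban=bool(props["is_urban"]),
            dhs_weight=float(props["dhs_weight"]),
            valid_coords=bool(props["valid_coords"]),
            true_point=tuple(tp) if tp else None,
        ))
    return out


def write_roads_geojson(roads: RoadNetwork, path: str | Path) -> None:
    feats = []
    for eid, e in zip(roads.edge_ids, roads.edges):
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": np.asarray(e, dtype=float).tolist()},
            "properties": {"edge_id": eid},
        })
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_roads_geojson(path: str | Path) -> RoadNetwork:
    data = json.loads(Path(path).read_text())
    edges, ids = [], []
    for feat in data["features"]:
        edges.append(np.asarray(feat["geometry"]["coordinates"], dtype=float))
        ids.append(int(feat["properties"]["edge_id"]))
    return RoadNetwork(edges, ids)
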