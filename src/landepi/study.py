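"""End-to-end study orchestration: simulate -> units -> classify -> metrics
-> aggregate -> model.

Every stage writes plain files (ASCII grid / GeoJSON / CSV / JSON); a run
with the same configuration and seed is byte-identical.  The default
configuration mirrors the emulated study conditions: 351 clusters of which
10 lack valid coordinates, 2 km / 5 km buffers, a 300 m land-cover grid
with a small contiguous urban class, 100 m population, 500 m lights with a
planted infrastructure-deficit rectangle over the densest urban core, and a
planted linear model for cluster prevalence with realistic effect sizes
for this kind of outcome.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate import (CONTROL_COLUMNS, aggregate_survey, assemble_table,
                        minmax_scale, write_feature_table)
from .diagnostics import lm_error_test, morans_i
from .metrics import compute_unit_metrics
from .models import OLSModel, SpatialError, SpatialLag, SpatialResults
from .raster import Raster
from .select import select_features
from .synth import (Cluster, RoadNetwork, SurveyTable, TruthRecord,
                    generate_clusters, generate_landcover, generate_nightlights,
                    generate_population, generate_roads, generate_survey,
                    make_deficit_rectangle, read_clusters_geojson,
                    write_clusters_geojson, write_roads_geojson)
from .units import (SpatialUnit, apply_inclusion, build_buffers, stratify_urban,
                    write_units_geojson)
from .urban import UrbanClassification, classify_urban
from .weights import SpatialWeights

__all__ = ["StudyConfig", "StudyReport", "simulate_world", "run_study",
           "run_pipeline", "validate_inputs"]

log = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    # world geometry
    extent_m: float = 60000.0
    landcover_cell_m: float = 300.0
    population_cell_m: float = 100.0
    lights_cell_m: float = 500.0
    class_spec: dict = field(default_factory=lambda: {
        "water": 0.05, "forest": 0.35, "cropland": 0.45, "urban": 0.15})
    landcover_smooth_sigma: float = 4.0
    # population / lights
    urban_density_mean: float = 120.0
    rural_density_mean: float = 4.0
    density_noise_sigma_log: float = 0.5
    density_primacy: float = 1.0
    lights_gain: float = 1.0
    lights_noise_frac: float = 0.02
    deficit_amplitude: float = 0.6
    deficit_area_fraction: float = 0.4
    # roads
    road_linearity: float = 1.2
    n_road_edges: int = 200
    # clusters
    n_clusters: int = 351
    urban_share: float = 0.5
    invalid_fraction: float = 10.0 / 351.0
    buffer_radii_m: tuple = (2000.0, 5000.0)
    # classification / metrics
    n_quantiles: int = 10
    connectivity: int = 8
    shape_variant: str = "per_patch"
    # modelling
    weights_scheme: str = "knn"
    knn_k: int = 8
    distance_band_m: float = 10000.0
    p_stepwise: float = 0.1
    p_spearman: float = 0.1
    alpha_significance: float = 0.05
    moran_inference: str = "analytic"
    # survey generation
    control_coupling: float = 1.0  # urbanisation -> controls slope factor
    # planted truth; the default carries a moderate spatial lag so the
    # emulated study, like the real one, exhibits significant positive
    # spatial autocorrelation of prevalence
    truth: TruthRecord = field(default_factory=lambda: TruthRecord(rho=0.45))

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "truth" in d and isinstance(d["truth"], dict):
            d["truth"] = TruthRecord(**d["truth"])
        if "buffer_radii_m" in d:
            d["buffer_radii_m"] = tuple(d["buffer_radii_m"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self, seed: int) -> str:
        payload = json.dumps({"config": self.to_dict(), "seed": seed},
                             sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _subseeds(seed: int, n: int = 8) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n)
    return [int(s & 0x7FFFFFFF) for s in state]


# ---------------------------------------------------------------------------
# simulation of the whole world


@dataclass
class World:
    landcover: Raster
    population: Raster
    lights: Raster
    deficit: Raster
    deficit_rect: tuple
    roads: RoadNetwork
    clusters: list[Cluster]
    survey: SurveyTable
    truth_frame: pd.DataFrame
    units: list[SpatialUnit]
    classification: UrbanClassification
    metrics: pd.DataFrame


def control_probabilities(units: list[SpatialUnit], seed: int,
                          noise_sd: float = 0.08,
                          coupling: float = 1.0) -> pd.DataFrame:
    """Cluster-level probabilities for the three control variables.

    Access to basic water/sanitation rises with the unit's urbanised
    fraction and the share of uneducated women falls with it (the usual
    pattern in urbanising settings), plus independent cluster-level noise.  ``coupling``
    scales the urbanisation slopes: 1 is the realistic default; 0 decouples
    the controls from urbanisation entirely (useful when a recovery
    experiment needs the exposure isolated from confounding).
    """
    rng = np.random.default_rng(seed)
    uf = np.array([u.urbanised_fraction for u in units])
    scale = uf / uf.max() if uf.max() > 0 else uf
    scale = coupling * scale
    n = len(units)
    water = np.clip(0.50 + 0.40 * scale + noise_sd * rng.standard_normal(n), 0.02, 0.98)
    sanit = np.clip(0.30 + 0.45 * scale + noise_sd * rng.standard_normal(n), 0.02, 0.98)
    noed = np.clip(0.55 - 0.40 * scale + noise_sd * rng.standard_normal(n), 0.02, 0.98)
    return pd.DataFrame({
        "pct_basic_water": water,
        "pct_basic_sanitation": sanit,
        "pct_women_no_education": noed,
    }, index=pd.Index([u.cluster_id for u in units], name="cluster_id"))


def simulate_world(config: StudyConfig, seed: int) -> World:
    """Generate every input layer plus the planted survey outcome."""
    s = _subseeds(seed)
    lc = generate_landcover(config.extent_m, config.landcover_cell_m,
                            config.class_spec, s[0],
                            smooth_sigma=config.landcover_smooth_sigma)
    pop = generate_population(lc, config.urban_density_mean,
                              config.rural_density_mean, s[1],
                              cell_size=config.population_cell_m,
                              noise_sigma_log=config.density_noise_sigma_log,
                              primacy=config.density_primacy)
    deficit, rect = make_deficit_rectangle(
        lc, pop, area_fraction=config.deficit_area_fraction,
        amplitude=config.deficit_amplitude)
    lights = generate_nightlights(pop, deficit, config.lights_gain, s[2],
                                  cell_size=config.lights_cell_m,
                                  noise_sd_frac=config.lights_noise_frac)
    roads = generate_roads(lc, config.road_linearity, s[3],
                           n_edges=config.n_road_edges)
    clusters = generate_clusters(lc, config.n_clusters, config.urban_share,
                                 s[4], displacement_m=config.buffer_radii_m,
                                 invalid_fraction=config.invalid_fraction)

    units = build_buffers(clusters, radii_m=config.buffer_radii_m)
    apply_inclusion(units, lc)
    stratify_urban(units)
    classification = classify_urban(lc, lights, pop, config.n_quantiles)
    metrics = compute_unit_metrics(units, lc, classification, roads,
                                   connectivity=config.connectivity,
                                   shape_variant=config.shape_variant)

    covs = control_probabilities(units, s[5], coupling=config.control_coupling)
    for col in config.truth.beta:
        if col in CONTROL_COLUMNS or col in covs.columns:
            continue
        series = metrics[col] if col in metrics.columns else pd.Series(dtype=float)
        covs[col] = series.reindex(covs.index).fillna(0.0)

    W = None
    if config.truth.rho != 0.0 or config.truth.lam != 0.0:
        pts = np.array([c.reported_point for c in clusters])
        W = SpatialWeights.from_knn(pts, k=config.knn_k).W
    survey, truth_frame = generate_survey(clusters, covs, config.truth, s[6], W=W)
    return World(lc, pop, lights, deficit, rect, roads, clusters, survey,
                 truth_frame, units, classification, metrics)


def build_feature_table(world: World) -> tuple[pd.DataFrame, dict, dict]:
    """Aggregate, join, and min/max-scale the modelling table."""
    aggregates = aggregate_survey(world.survey)
    table, manifest = assemble_table(world.units, world.metrics, aggregates)
    scale_cols = CONTROL_COLUMNS + manifest["independents"]
    scaled, record = minmax_scale(table, scale_cols)
    manifest["independents"] = [c for c in manifest["independents"]
                                if c in scaled.columns]
    manifest["controls"] = [c for c in CONTROL_COLUMNS if c in scaled.columns]
    return scaled, manifest, record


# ---------------------------------------------------------------------------
# the stratified study


@dataclass
class StratumReport:
    stratum: str
    n: int
    morans_i: float
    morans_p: float
    lm_error_stat: float
    lm_error_p: float
    selection_trace: dict
    selected_features: list[str]
    results: dict[str, SpatialResults]
    skipped: bool = False
    skip_reason: str = ""


@dataclass
class StudyReport:
    config_hash: str
    seed: int
    weights_scheme: str
    strata: dict[str, StratumReport]

    def records(self) -> pd.DataFrame:
        """One row per variable x model x stratum (regression-table layout)."""
        rows = []
        for sname, rep in self.strata.items():
            if rep.skipped:
                continue
            for mname, res in rep.results.items():
                for var in res.params.index:
                    rows.append({
                        "stratum": sname, "model": mname, "variable": var,
                        "coef": res.params[var], "se": res.bse[var],
                        "p": res.pvalues[var],
                        "vif": res.diagnostics.get("vif", {}).get(var, np.nan),
                        "r2": res.rsquared, "aic": res.aic,
                        "jb": res.diagnostics["jarque_bera"][0],
                        "jb_p": res.diagnostics["jarque_bera"][1],
                        "bp": res.diagnostics["breusch_pagan"][0],
                        "bp_p": res.diagnostics["breusch_pagan"][1],
                        "rho": res.rho if res.rho is not None else np.nan,
                        "lambda": res.lam if res.lam is not None else np.nan,
                        "n": res.nobs,
                    })
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        out = {"config_hash": self.config_hash, "seed": self.seed,
               "weights_scheme": self.weights_scheme, "strata": {}}
        for sname, rep in self.strata.items():
            sd = {
                "n": rep.n, "skipped": rep.skipped, "skip_reason": rep.skip_reason,
                "morans_i": rep.morans_i, "morans_p": rep.morans_p,
                "lm_error_stat": rep.lm_error_stat, "lm_error_p": rep.lm_error_p,
                "selected_features": rep.selected_features,
                "selection_trace": rep.selection_trace,
                "models": {},
            }
            for mname, res in rep.results.items():
                sd["models"][mname] = {
                    "params": {k: float(v) for k, v in res.params.items()},
                    "bse": {k: float(v) for k, v in res.bse.items()},
                    "pvalues": {k: float(v) for k, v in res.pvalues.items()},
                    "r2": res.rsquared, "aic": res.aic, "llf": res.llf,
                    "rho": res.rho, "rho_se": res.rho_se,
                    "lambda": res.lam, "lambda_se": res.lam_se,
                    "diagnostics": res.diagnostics,
                }
            out["strata"][sname] = sd
        return out

    def text(self) -> str:
        lines = [f"study report  (config {self.config_hash}, seed {self.seed}, "
                 f"W: {self.weights_scheme})"]
        for sname, rep in self.strata.items():
            lines.append("")
            lines.append(f"== stratum: {sname} (N = {rep.n}) ==")
            if rep.skipped:
                lines.append(f"  skipped: {rep.skip_reason}")
                continue
            lines.append(f"  Moran's I(y) = {rep.morans_i:.4f} (p = {rep.morans_p:.4f})")
            lines.append(f"  LM-error = {rep.lm_error_stat:.4f} (p = {rep.lm_error_p:.4f})")
            lines.append(f"  selected: {rep.selected_features}")
            for res in rep.results.values():
                lines.append("")
                lines.append(res.summary())
        return "\n".join(lines) + "\n"


def _fit_four_models(table: pd.DataFrame, features: list[str],
                     w: SpatialWeights) -> dict[str, SpatialResults]:
    y = table["prevalence"]
    X = table[features]
    weights = table["dhs_weight"].to_numpy(dtype=float)
    return {
        "unweighted_ols": OLSModel(y, X).fit(),
        "weighted_ols": OLSModel(y, X, weights=weights).fit(),
        "spatial_lag": SpatialLag(y, X, w).fit(),
        "spatial_error": SpatialError(y, X, w).fit(),
    }


def run_study(table: pd.DataFrame, manifest: dict, config: StudyConfig,
              seed: int, unit_coords: dict[int, tuple[float, float]]) -> StudyReport:
    """Stratified analysis: Moran's I, two-filter selection, four models.

    ``unit_coords`` maps cluster_id to the unit centroid used for W.
    """
    controls = manifest["controls"]
    candidates = manifest["independents"]
    strata = {"full": table, "urban": table[table["in_urban_subset"]]}
    out: dict[str, StratumReport] = {}
    for sname, sub in strata.items():
        n = len(sub)
        min_n = len(controls) + 6
        if n < min_n:
            out[sname] = StratumReport(sname, n, np.nan, np.nan, np.nan, np.nan,
                                       {}, [], {}, skipped=True,
                                       skip_reason=f"N = {n} < {min_n}")
            log.warning("stratum %s skipped (N = %d)", sname, n)
            continue
        coords = np.array([unit_coords[c] for c in sub.index])
        if config.weights_scheme == "knn":
            w = SpatialWeights.from_knn(coords, k=min(config.knn_k, n - 1))
        else:
            w = SpatialWeights.from_distance_band(coords, config.distance_band_m)
        y = sub["prevalence"].to_numpy(dtype=float)
        mi, mp = morans_i(y, w, inference=config.moran_inference, seed=seed)
        trace = select_features(sub, "prevalence", candidates,
                                always_in=controls,
                                p_stepwise=config.p_stepwise,
                                p_spearman=config.p_spearman, seed=seed)
        features = controls + trace.surviving
        results = _fit_four_models(sub, features, w)
        lm_stat, lm_p = lm_error_test(results["unweighted_ols"].resid, w)
        out[sname] = StratumReport(
            stratum=sname, n=n, morans_i=mi, morans_p=mp,
            lm_error_stat=lm_stat, lm_error_p=lm_p,
            selection_trace={"steps": trace.steps,
                             "spearman": {k: list(v) for k, v in trace.spearman.items()}},
            selected_features=trace.surviving, results=results,
        )
    return StudyReport(config_hash=config.hash(seed), seed=seed,
                       weights_scheme=(f"knn:{config.knn_k}"
                                       if config.weights_scheme == "knn"
                                       else f"distance_band:{config.distance_band_m:g}"),
                       strata=out)


# ---------------------------------------------------------------------------
# full pipeline with file outputs


def run_pipeline(config: StudyConfig, seed: int, outdir: str | Path) -> StudyReport:
    """simulate -> units -> classify -> metrics -> aggregate -> model.

    Writes every stage's artefacts under ``outdir`` and returns the report.
    Rerunning with the same config and seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.hash(seed)
    world = simulate_world(config, seed)

    world.landcover.write_ascii(outdir / "landcover.asc")
    world.population.write_ascii(outdir / "population.asc")
    world.lights.write_ascii(outdir / "lights.asc")
    world.deficit.write_ascii(outdir / "deficit.asc")
    write_clusters_geojson(world.clusters, outdir / "clusters.geojson")
    write_roads_geojson(world.roads, outdir / "roads.geojson")
    write_units_geojson(world.units, outdir / "units.geojson")
    world.classification.class_grid.write_ascii(outdir / "urban_classes.asc")
    world.metrics.to_csv(outdir / "unit_metrics.csv")
    world.survey.write_csv(outdir / "households.csv", outdir / "women.csv")
    config.truth.to_json(outdir / "truth.json")

    table, manifest, record = build_feature_table(world)
    manifest["config_hash"] = chash
    write_feature_table(table, manifest, record, outdir)

    unit_coords = {u.cluster_id: (u.polygon.centroid.x, u.polygon.centroid.y)
                   for u in world.units}
    report = run_study(table, manifest, config, seed, unit_coords)
    (outdir / "report.json").write_text(
        json.dumps(report.to_json_dict(), indent=1, sort_keys=True))
    report.records().to_csv(outdir / "report_records.csv", index=False)
    (outdir / "report.txt").write_text(report.text())
    counts = {
        "config_hash": chash,
        "n_clusters": len(world.clusters),
        "n_invalid_coords": sum(not c.valid_coords for c in world.clusters),
        "n_no_urban_pixel": sum(1 for u in world.units
                                if u.cluster.valid_coords and not u.included),
        "n_included": sum(u.included for u in world.units),
        "n_urban_subset": sum(u.in_urban_subset for u in world.units),
        "n_modelled": int(len(table)),
    }
    (outdir / "counts.json").write_text(json.dumps(counts, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# input validation


def validate_inputs(paths: dict[str, str | Path]) -> list[dict]:
    """Schema and extent checks on a directory of pipeline inputs.

    ``paths`` may contain keys landcover, lights, population, clusters.
    Returns a list of problem records (empty when all is well).
    """
    problems: list[dict] = []
    rasters: dict[str, Raster] = {}
    for key in ("landcover", "lights", "population"):
        if key not in paths:
            continue
        p = Path(paths[key])
        if not p.exists():
            problems.append({"severity": "error", "layer": key,
                             "message": f"missing file {p}"})
            continue
        try:
            rasters[key] = Raster.read_ascii(p)
        except Exception as exc:  # malformed header or data
            problems.append({"severity": "error", "layer": key,
                             "message": f"unreadable raster: {exc}"})
    if "landcover" in rasters and rasters["landcover"].legend is None:
        problems.append({"severity": "error", "layer": "landcover",
                         "message": "landcover raster has no class legend"})
    clusters = None
    if "clusters" in paths:
        p = Path(paths["clusters"])
        if not p.exists():
            problems.append({"severity": "error", "layer": "clusters",
                             "message": f"missing file {p}"})
        else:
            try:
                clusters = read_clusters_geojson(p)
            except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
                problems.append({"severity": "error", "layer": "clusters",
                                 "message": f"schema error: {exc}"})
    if clusters and "landcover" in rasters:
        lc = rasters["landcover"]
        x0, y0, x1, y1 = lc.extent
        outside = []
        for c in clusters:
            if not c.valid_coords:
                continue
            r = 2000.0 if c.is_urban else 5000.0
            x, y = c.reported_point
            if x - r < x0 or x + r > x1 or y - r < y0 or y + r > y1:
                outside.append(c.cluster_id)
        if outside:
            problems.append({"severity": "warning", "layer": "landcover",
                             "message": "raster does not cover buffers of units "
                                        f"{outside[:20]}"})
    for key, rast in rasters.items():
        if not rast.mask.any():
            problems.append({"severity": "warning", "layer": key,
                             "message": "raster is entirely nodata"})
    return problems
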