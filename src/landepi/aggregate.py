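"""Cluster-level aggregation of survey records and assembly of the feature table.

Aggregates are proportions, with population (person) denominators: diarrhoea
prevalence is cases over under-fives, service access is members of flagged
households over all members, education is the share of women aged 15-49
without schooling.  The modelling table joins these with the landscape
metric battery on cluster_id, keeps included units only, and is min/max
scaled so coefficients are comparable across features.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import SurveyTable
from .units import SpatialUnit

__all__ = ["aggregate_survey", "assemble_table", "minmax_scale",
           "inverse_minmax", "CONTROL_COLUMNS"]

log = logging.getLogger(__name__)

CONTROL_COLUMNS = ["pct_basic_water", "pct_basic_sanitation", "pct_women_no_education"]


def aggregate_survey(survey: SurveyTable, household_weighted: bool = False) -> pd.DataFrame:
    """Per-cluster outcome and control aggregates.

    Returns a DataFrame indexed by cluster_id with columns prevalence,
    pct_basic_water, pct_basic_sanitation, pct_women_no_education,
    n_under5.  Prevalence is NaN where a cluster has no under-fives (the
    unit is dropped later, with a log entry).  Service shares are
    person-weighted by default (population denominators); set
    ``household_weighted`` to weight each household equally instead.
    """
    hh = survey.households
    g = hh.groupby("cluster_id")
    under5 = g["n_under5"].sum()
    cases = g["n_diarrhoea_cases"].sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        prevalence = cases / under5.replace(0, np.nan)

    def service_share(flag_col: str) -> pd.Series:
        if household_weighted:
            return g[flag_col].mean()
        flagged = hh.assign(_fm=hh.n_members * hh[flag_col]).groupby("cluster_id")["_fm"].sum()
        return flagged / g["n_members"].sum()

    out = pd.DataFrame({
        "prevalence": prevalence,
        "pct_basic_water": service_share("basic_water"),
        "pct_basic_sanitation": service_share("basic_sanitation"),
        "n_under5": under5,
    })
    women = survey.women
    if len(women):
        out["pct_women_no_education"] = women.groupby("cluster_id")["no_education"].mean()
    else:
        out["pct_women_no_education"] = np.nan
    out.index.name = "cluster_id"
    return out[["prevalence"] + CONTROL_COLUMNS + ["n_under5"]]


def assemble_table(units: list[SpatialUnit], unit_metrics: pd.DataFrame,
                   survey_aggregates: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Inner-join of included units, their metrics, and survey aggregates.

    Returns (table, manifest).  The table is indexed by cluster_id and holds
    the dependent variable ``prevalence``, the three controls, every metric
    column, ``dhs_weight`` and ``in_urban_subset``.  Units with undefined
    prevalence are dropped (logged).  Duplicate cluster ids raise.
    """
    included = [u for u in units if u.included]
    ids = [u.cluster_id for u in included]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate cluster_id among included units")
    missing_m = [i for i in ids if i not in unit_metrics.index]
    if missing_m:
        raise ValueError(f"units missing landscape metrics: {missing_m}")
    missing_s = [i for i in ids if i not in survey_aggregates.index]
    if missing_s:
        raise ValueError(f"units missing survey aggregates: {missing_s}")

    base = pd.DataFrame({
        "dhs_weight": [u.cluster.dhs_weight for u in included],
        "in_urban_subset": [u.in_urban_subset for u in included],
        "urbanised_fraction": [u.urbanised_fraction for u in included],
    }, index=pd.Index(ids, name="cluster_id"))
    table = base.join(survey_aggregates, how="inner").join(unit_metrics, how="inner")

    n_before = len(table)
    table = table[table["prevalence"].notna()]
    dropped = n_before - len(table)
    if dropped:
        log.info("dropped %d unit(s) with undefined prevalence (no under-fives)",
                 dropped)
    metric_cols = [c for c in unit_metrics.columns]
    manifest = {
        "dependent": "prevalence",
        "controls": CONTROL_COLUMNS,
        "independents": metric_cols,
        "weight": "dhs_weight",
        "subset_flag": "in_urban_subset",
        "n_units": int(len(table)),
        "n_dropped_undefined_y": int(dropped),
    }
    return table, manifest


def minmax_scale(table: pd.DataFrame, columns: list[str]) -> tuple[pd.DataFrame, dict]:
    """Scale columns to [0, 1] by x' = (x - min) / (max - min).

    Constant columns are dropped with a warning (their coefficient would be
    undefined).  Returns the scaled table and a record {col: (min, max)}
    for the inverse transform.
    """
    out = table.copy()
    record: dict[str, tuple[float, float]] = {}
    for col in columns:
        lo = float(out[col].min())
        hi = float(out[col].max())
        if hi == lo:
            warnings.warn(f"constant column {col!r} dropped from scaling")
            out = out.drop(columns=[col])
            continue
        out[col] = (out[col] - lo) / (hi - lo)
        record[col] = (lo, hi)
    return out, record


def inverse_minmax(scaled: pd.DataFrame, record: dict) -> pd.DataFrame:
    out = scaled.copy()
    for col, (lo, hi) in record.items():
        if col in out.columns:
            out[col] = out[col] * (hi - lo) + lo
    return out


def write_feature_table(table: pd.DataFrame, manifest: dict, record: dict,
                        outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "feature_table.csv")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (outdir / "scaling.json").write_text(json.dumps(record, indent=1))
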