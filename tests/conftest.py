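import pytest

from landepi.raster import Raster
from landepi.study import StudyConfig
from landepi.synth import TruthRecord, generate_landcover, generate_population


SMALL_CLASS_SPEC = {"water": 0.05, "forest": 0.35, "cropland": 0.40, "urban": 0.20}


@pytest.fixture(scope="session")
def small_landcover() -> Raster:
    """30 km world, 100x100 land-cover grid with a contiguous urban class."""
    return generate_landcover(30000, 300, SMALL_CLASS_SPEC, seed=7)


@pytest.fixture(scope="session")
def small_population(small_landcover) -> Raster:
    return generate_population(small_landcover, urban_mean=120, rural_mean=4, seed=11)


@pytest.fixture(scope="session")
def small_config() -> StudyConfig:
    """A compact configuration for end-to-end tests."""
    return StudyConfig(
        extent_m=30000.0,
        class_spec=dict(SMALL_CLASS_SPEC),
        n_clusters=60,
        invalid_fraction=0.05,
        n_road_edges=60,
    )


@pytest.fixture(scope="session")
def recovery_truth() -> TruthRecord:
    """Planted truth for sign-recovery experiments: a clearly detectable
    positive dense-precarious effect and negative sanitation effect, with
    survey sizes large enough that cluster prevalence is measured well
    (binomial noise below the planted per-unit effects)."""
    return TruthRecord(
        alpha=0.30,
        beta={"pct_basic_water": 0.0, "pct_basic_sanitation": -0.25,
              "pct_women_no_education": -0.10,
              "dense_precarious_area_frac": 0.45},
        noise_sd=0.03,
        households_per_cluster=100,
    )
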