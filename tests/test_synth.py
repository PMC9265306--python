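import numpy as np
import pytest
from scipy import stats

from landepi.raster import Raster, resample
from landepi.synth import (Cluster, TruthRecord, edge_chord, edge_length,
                           generate_clusters, generate_landcover,
                           generate_nightlights, generate_population,
                           generate_roads, generate_survey,
                           make_deficit_rectangle, read_clusters_geojson,
                           read_roads_geojson, urban_mask,
                           write_clusters_geojson, write_roads_geojson)
from landepi.weights import SpatialWeights
from landepi.diagnostics import morans_i
import landepi.study as study


class TestLandcover:
    def test_degenerate_single_class(self):
        lc = generate_landcover(3000, 300, {"urban": 1.0}, seed=0)
        assert (lc.values == 1).all()

    def test_fractions_within_two_points(self):
        lc = generate_landcover(30000, 300, {"urban": 0.2, "crop": 0.8}, seed=7)
        frac = urban_mask(lc).mean()
        assert 0.18 <= frac <= 0.22

    def test_urban_blobs_are_contiguous_not_salt_and_pepper(self):
        from scipy import ndimage
        lc = generate_landcover(30000, 300, {"urban": 0.2, "crop": 0.8}, seed=7)
        um = urban_mask(lc)
        _, n_components = ndimage.label(um)
        # 2000 urban pixels scattered i.i.d. would give hundreds of components
        assert n_components < 30

    def test_same_seed_identical(self):
        a = generate_landcover(9000, 300, {"urban": 0.3, "crop": 0.7}, seed=5)
        b = generate_landcover(9000, 300, {"urban": 0.3, "crop": 0.7}, seed=5)
        assert np.array_equal(a.values, b.values)

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_landcover(3000, 300, {"urban": 0.5, "crop": 0.4}, seed=0)


class TestPopulation:
    def test_stratum_mean_ratio(self, small_landcover):
        pop = generate_population(small_landcover, 100.0, 1.0, seed=3, primacy=0.0)
        lc_fine = resample(small_landcover, pop, "nearest")
        urb = lc_fine.values == max(small_landcover.legend)
        ratio = pop.values[urb].mean() / pop.values[~urb & pop.mask].mean()
        assert 80 <= ratio <= 120

    def test_equal_means_indistinguishable(self, small_landcover):
        pop = generate_population(small_landcover, 10.0, 10.0, seed=3, primacy=0.0)
        lc_fine = resample(small_landcover, pop, "nearest")
        urb = lc_fine.values == max(small_landcover.legend)
        gap = abs(pop.values[urb].mean() - pop.values[~urb].mean())
        assert gap < 0.15 * pop.values.mean()

    def test_negative_mean_rejected(self, small_landcover):
        with pytest.raises(ValueError):
            generate_population(small_landcover, -1.0, 1.0, seed=0)

    def test_all_nodata_propagates(self):
        lc = Raster(np.full((4, 4), -9999.0), 300.0, nodata=-9999.0,
                    kind="landcover", legend={1: "urban"})
        pop = generate_population(lc, 10.0, 1.0, seed=0)
        assert not pop.mask.any()

    def test_primacy_makes_largest_agglomeration_densest(self, small_landcover):
        from scipy import ndimage
        pop = generate_population(small_landcover, 100.0, 1.0, seed=3, primacy=1.0)
        dens300 = resample(pop, small_landcover, "area_weighted_mean")
        um = urban_mask(small_landcover)
        labels, n = ndimage.label(um)
        sizes = ndimage.sum_labels(um, labels, index=range(1, n + 1))
        big = labels == (1 + int(np.argmax(sizes)))
        small = um & ~big
        assert small.any()
        assert dens300.values[big].mean() > dens300.values[small].mean()


class TestNightlights:
    def test_zero_deficit_lights_track_density(self, small_landcover, small_population):
        zero = small_landcover.blank_like(0.0)
        li = generate_nightlights(small_population, zero, gain=1.0, seed=1)
        dens = resample(small_population, li, "area_weighted_mean")
        rho = stats.spearmanr(li.values.ravel(), dens.values.ravel()).statistic
        assert rho > 0.9

    def test_total_deficit_gives_noise_floor(self, small_landcover, small_population):
        one = small_landcover.blank_like(1.0)
        li = generate_nightlights(small_population, one, gain=1.0, seed=1)
        dens = resample(small_population, li, "area_weighted_mean")
        assert li.values.mean() < 0.05 * dens.values.mean()

    def test_deficit_rectangle_darkens_it(self, small_landcover, small_population):
        deficit, rect = make_deficit_rectangle(small_landcover, small_population,
                                               area_fraction=0.3, amplitude=1.0)
        li = generate_nightlights(small_population, deficit, gain=1.0, seed=2)
        dens = resample(small_population, li, "area_weighted_mean")
        X, Y = li.cell_centers()
        xmin, ymin, xmax, ymax = rect
        inside = (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
        # compare light per unit density inside vs outside
        per_dens_in = li.values[inside].sum() / dens.values[inside].sum()
        per_dens_out = li.values[~inside].sum() / dens.values[~inside].sum()
        assert per_dens_in < 0.5 * per_dens_out

    def test_deficit_out_of_range_rejected(self, small_landcover, small_population):
        bad = small_landcover.blank_like(1.5)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            generate_nightlights(small_population, bad, gain=1.0, seed=0)


class TestRoads:
    def test_straight_roads_at_target_one(self, small_landcover):
        net = generate_roads(small_landcover, 1.0, seed=4, n_edges=40)
        for e in net.edges:
            assert edge_length(e) == pytest.approx(edge_chord(e))

    def test_mean_linearity_near_target(self, small_landcover):
        net = generate_roads(small_landcover, 1.4, seed=4, n_edges=60)
        lins = [edge_length(e) / edge_chord(e) for e in net.edges]
        assert 1.3 <= np.mean(lins) <= 1.5

    def test_no_urban_pixels_error(self):
        lc = Raster(np.ones((5, 5)), 300.0, kind="landcover", legend={1: "crop"})
        with pytest.raises(ValueError, match="urban"):
            generate_roads(lc, 1.2, seed=0)

    def test_roads_concentrate_on_urban(self, small_landcover):
        net = generate_roads(small_landcover, 1.0, seed=4, n_edges=50)
        um = urban_mask(small_landcover)
        X, Y = small_landcover.cell_centers()
        cs = small_landcover.cell_size
        on_urban = 0
        for e in net.edges:
            x, y = e[0]
            d = np.hypot(X[um] - x, Y[um] - y)
            on_urban += d.min() < cs
        assert on_urban == len(net.edges)  # endpoints are urban pixel centres


class TestClusters:
    def test_displacement_radii_respected(self, small_landcover):
        cls = generate_clusters(small_landcover, 80, urban_share=0.5, seed=9)
        for c in cls:
            d = np.hypot(c.reported_point[0] - c.true_point[0],
                         c.reported_point[1] - c.true_point[1])
            assert d <= (2000.0 if c.is_urban else 5000.0) + 1e-9

    def test_zero_displacement_reported_equals_true(self, small_landcover):
        cls = generate_clusters(small_landcover, 10, 0.5, seed=9,
                                displacement_m=(0.0, 0.0))
        for c in cls:
            assert c.reported_point == pytest.approx(c.true_point)

    def test_exact_invalid_count_emulation(self, small_landcover):
        cls = generate_clusters(small_landcover, 351, 0.5, seed=9,
                                invalid_fraction=10 / 351)
        assert sum(not c.valid_coords for c in cls) == 10

    def test_urban_clusters_sit_on_urban_pixels(self, small_landcover):
        cls = generate_clusters(small_landcover, 40, urban_share=1.0, seed=2)
        um = urban_mask(small_landcover)
        X, Y = small_landcover.cell_centers()
        for c in cls:
            d = np.hypot(X[um] - c.true_point[0], Y[um] - c.true_point[1])
            assert d.min() < 1e-6
            # hence reported point within 2 km (+ half-pixel) of an urban centre
            dr = np.hypot(X[um] - c.reported_point[0], Y[um] - c.reported_point[1])
            assert dr.min() <= 2000.0 + 1e-9

    def test_determinism_and_share_bounds(self, small_landcover):
        a = generate_clusters(small_landcover, 30, 0.5, seed=3)
        b = generate_clusters(small_landcover, 30, 0.5, seed=3)
        assert [c.reported_point for c in a] == [c.reported_point for c in b]
        with pytest.raises(ValueError):
            generate_clusters(small_landcover, 30, 1.5, seed=3)


class TestSurvey:
    def _covs(self, clusters, x=None):
        import pandas as pd
        idx = pd.Index([c.cluster_id for c in clusters], name="cluster_id")
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "pct_basic_water": rng.uniform(0.3, 0.9, len(idx)),
            "pct_basic_sanitation": rng.uniform(0.2, 0.8, len(idx)),
            "pct_women_no_education": rng.uniform(0.1, 0.7, len(idx)),
        }, index=idx)
        df["dense_precarious_area_frac"] = (x if x is not None
                                            else rng.uniform(0, 0.3, len(idx)))
        return df

    def test_structural_invariants(self, small_landcover):
        cls = generate_clusters(small_landcover, 20, 0.5, seed=1)
        truth = TruthRecord()
        table, _ = generate_survey(cls, self._covs(cls), truth, seed=2)
        table.validate()
        hh = table.households
        assert (hh.n_diarrhoea_cases <= hh.n_under5).all()
        assert (hh.n_under5 <= hh.n_members).all()

    def test_null_model_prevalences_cluster_around_alpha(self, small_landcover):
        cls = generate_clusters(small_landcover, 40, 0.5, seed=1)
        truth = TruthRecord(alpha=0.2, beta={"dense_precarious_area_frac": 0.0},
                            noise_sd=0.0)
        _, tf = generate_survey(cls, self._covs(cls), truth, seed=3)
        assert np.allclose(tf.latent_prevalence, 0.2)

    def test_spatial_lag_truth_produces_positive_morans_i(self, small_landcover):
        cls = generate_clusters(small_landcover, 80, 0.5, seed=1)
        pts = np.array([c.reported_point for c in cls])
        w = SpatialWeights.from_knn(pts, k=8)
        covs = self._covs(cls)
        hits = 0
        n_rep = 25
        for s in range(n_rep):
            truth = TruthRecord(alpha=0.3, beta={"dense_precarious_area_frac": 0.0},
                                rho=0.5, noise_sd=0.1)
            _, tf = generate_survey(cls, covs, truth, seed=100 + s, W=w.W)
            i, p = morans_i(tf.latent_prevalence.to_numpy(), w)
            hits += (i > 0) and (p < 0.05)
        assert hits >= 0.9 * n_rep

    def test_lag_and_error_cannot_both_be_set(self):
        with pytest.raises(ValueError):
            TruthRecord(rho=0.5, lam=0.5)


class TestGeoJsonRoundtrip:
    def test_clusters(self, small_landcover, tmp_path):
        cls = generate_clusters(small_landcover, 15, 0.4, seed=6,
                                invalid_fraction=0.2)
        p = tmp_path / "c.geojson"
        write_clusters_geojson(cls, p)
        back = read_clusters_geojson(p)
        assert [c.cluster_id for c in back] == [c.cluster_id for c in cls]
        assert all(a.reported_point == pytest.approx(b.reported_point)
                   for a, b in zip(back, cls))
        assert [c.valid_coords for c in back] == [c.valid_coords for c in cls]

    def test_roads(self, small_landcover, tmp_path):
        net = generate_roads(small_landcover, 1.3, seed=6, n_edges=10)
        p = tmp_path / "r.geojson"
        write_roads_geojson(net, p)
        back = read_roads_geojson(p)
        assert back.total_length() == pytest.approx(net.total_length())
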