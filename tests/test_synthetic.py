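import numpy as np
import pytest
import shapely
from scipy import stats
from shapely.geometry import Point

from habsuit import (LandscapeConfig, define_true_suitability, generate_dem,
                     generate_geology, generate_precipitation,
                     generate_spectral_bands, generate_survey_cells,
                     sample_virtual_species)
from habsuit.terrain import soil_color_index


class TestDem:
    def test_zero_amplitude_gives_constant_elevation(self, small_config):
        cfg = LandscapeConfig(extent=small_config.extent,
                              relief_amplitude_m=0.0, seed=1)
        dem = generate_dem(cfg)
        assert np.ptp(dem.values) == 0.0

    def test_same_seed_bit_identical(self, small_config):
        a = generate_dem(small_config)
        b = generate_dem(small_config)
        np.testing.assert_array_equal(a.values, b.values)

    def test_relief_amplitude_scales_variance(self):
        # Monte-Carlo over seeds: amplitude 10 must beat amplitude 1
        var10, var1 = [], []
        for seed in range(50):
            for amp, acc in ((10.0, var10), (1.0, var1)):
                cfg = LandscapeConfig(extent=(0, 0, 40, 40),
                                      relief_amplitude_m=amp, seed=seed)
                acc.append(generate_dem(cfg).values.var())
        assert np.mean(var10) > np.mean(var1)
        assert min(var10) > max(var1)

    def test_lower_roughness_means_smoother_surface(self):
        def lag1_corr(vals):
            a = vals[:, :-1].ravel()
            b = vals[:, 1:].ravel()
            return np.corrcoef(a, b)[0, 1]

        smooth = generate_dem(LandscapeConfig(extent=(0, 0, 100, 100),
                                              roughness=0.5, seed=2))
        rough = generate_dem(LandscapeConfig(extent=(0, 0, 100, 100),
                                             roughness=8.0, seed=2))
        assert lag1_corr(smooth.values) > lag1_corr(rough.values)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(extent=(0, 0, 0, 100))
        with pytest.raises(ValueError):
            LandscapeConfig(cell_size_m=-1)
        with pytest.raises(ValueError):
            LandscapeConfig(extent=(0, 0, 100.5, 100), cell_size_m=1.0)


class TestGeology:
    def test_mask_fraction_near_target(self, small_config):
        _, mask = generate_geology(small_config)
        share = mask.values.mean()
        assert 0.24 <= share <= 0.36  # 0.3 +/- 20%

    def test_vector_and_mask_agree_at_cell_centers(self):
        cfg = LandscapeConfig(extent=(0, 0, 50, 50), formation_fraction=0.25,
                              seed=4)
        polygons, mask = generate_geology(cfg)
        union = shapely.union_all(polygons)
        xs, ys = mask.cell_centers()
        for r in range(mask.nrows):
            for c in range(mask.ncols):
                inside = union.contains(Point(xs[c], ys[r]))
                assert inside == bool(mask.values[r, c] > 0.5)

    def test_polygons_lie_within_extent(self, small_config):
        polygons, _ = generate_geology(small_config)
        x0, y0, x1, y1 = small_config.extent
        for p in polygons:
            bx0, by0, bx1, by1 = p.bounds
            assert bx0 >= x0 - 1e-6 and by0 >= y0 - 1e-6
            assert bx1 <= x1 + 1e-6 and by1 <= y1 + 1e-6


class TestPrecipitation:
    def test_endpoints_match_requested_range(self, small_config):
        p = generate_precipitation(small_config, 220.0, 320.0)
        assert p.values.min() == 220.0
        assert p.values.max() == 320.0

    def test_row_means_monotone_north_to_south(self, small_config):
        p = generate_precipitation(small_config, 220.0, 320.0)
        row_means = p.values.mean(axis=1)
        assert np.all(np.diff(row_means) > 0)  # row 0 = north = driest

    def test_degenerate_gradient_near_constant(self, small_config):
        p = generate_precipitation(small_config, 250.0, 250.0 + 1e-9)
        assert np.ptp(p.values) <= 1e-9

    def test_rejects_inverted_range(self, small_config):
        with pytest.raises(ValueError):
            generate_precipitation(small_config, 320.0, 220.0)


class TestSpectralBands:
    def test_noise_free_index_values(self, small_config):
        _, mask = generate_geology(small_config)
        red, green = generate_spectral_bands(mask, noise_sd=0.0, seed=0)
        idx = soil_color_index(red, green)
        on = mask.values > 0.5
        assert np.allclose(idx.values[on], 0.5)
        assert np.allclose(idx.values[~on], 0.0)

    def test_reproducible_and_separated_at_moderate_noise(self, small_config):
        _, mask = generate_geology(small_config)
        r1, g1 = generate_spectral_bands(mask, noise_sd=0.02, seed=7)
        r2, g2 = generate_spectral_bands(mask, noise_sd=0.02, seed=7)
        np.testing.assert_array_equal(r1.values, r2.values)
        np.testing.assert_array_equal(g1.values, g2.values)
        idx = soil_color_index(r1, g1)
        on = mask.values > 0.5
        assert idx.values[on].mean() > idx.values[~on].mean()


class TestTruth:
    def test_zero_model_gives_half_everywhere(self, flat_raster):
        truth = define_true_suitability({"z": flat_raster}, {"z": 0.0}, 0.0)
        assert np.allclose(truth.suitability.values, 0.5)

    def test_logistic_tail(self, flat_raster):
        truth = define_true_suitability({"z": flat_raster}, {"z": 0.0}, -10.0)
        assert np.all(truth.suitability.values < 1e-4)

    def test_monotone_in_single_covariate(self):
        rng = np.random.default_rng(3)
        from habsuit import GridRaster
        layer = GridRaster(rng.normal(size=(15, 15)), 0, 0, 1.0)
        truth = define_true_suitability({"z": layer}, {"z": 1.0}, 0.0)
        order = np.argsort(layer.values.ravel())
        suit_sorted = truth.suitability.values.ravel()[order]
        assert np.all(np.diff(suit_sorted) > 0)

    def test_missing_layer_rejected(self, flat_raster):
        with pytest.raises(ValueError):
            define_true_suitability({"z": flat_raster}, {"w": 1.0}, 0.0)


class TestVirtualSpecies:
    def test_empty_request_empty_output(self, flat_raster):
        truth = define_true_suitability({"z": flat_raster}, {"z": 0.0}, 0.0)
        points, polygons = sample_virtual_species(truth, 0, 0, 10.0, seed=0)
        assert points == [] and polygons == []

    def test_uniform_truth_gives_uniform_points(self):
        from habsuit import GridRaster
        flat = GridRaster(np.zeros((100, 100)), 0, 0, 1.0)
        truth = define_true_suitability({"z": flat}, {"z": 0.0}, 0.0)
        points, _ = sample_virtual_species(truth, 2000, 0, 0.0, seed=42)
        x = np.array([p.x for p in points])
        y = np.array([p.y for p in points])
        # chi-square GOF on a 5x5 quadrat grid
        counts, _, _ = np.histogram2d(x, y, bins=5, range=[[0, 100], [0, 100]])
        stat = ((counts - 80.0) ** 2 / 80.0).sum()
        p = stats.chi2.sf(stat, df=24)
        assert p > 0.01

    def test_support_restriction(self):
        from habsuit import GridRaster
        vals = np.full((20, 20), -50.0)
        vals[5:8, 5:8] = 50.0  # suitability ~1 only in the patch
        layer = GridRaster(vals, 0, 0, 1.0)
        truth = define_true_suitability({"z": layer}, {"z": 300.0}, 0.0)
        points, _ = sample_virtual_species(truth, 200, 0, 0.0, seed=1)
        rows, cols = zip(*[layer.index_of(p.x, p.y) for p in points])
        assert set(np.unique(rows)) <= {5, 6, 7}
        assert set(np.unique(cols)) <= {5, 6, 7}


class TestSurveyCells:
    def _truth(self, n=100):
        rng = np.random.default_rng(5)
        from habsuit import GridRaster
        layer = GridRaster(rng.normal(size=(n, n)), 0, 0, 1.0)
        return define_true_suitability({"z": layer}, {"z": 2.0}, 0.0)

    def test_detection_rules_zero_and_one(self):
        truth = self._truth()
        cells0 = generate_survey_cells(truth.suitability, n_cells=4, seed=0,
                                       detection_rule=lambda t: 0.0)
        assert cells0.cells["detected"].sum() == 0
        cells1 = generate_survey_cells(truth.suitability, n_cells=4, seed=0,
                                       detection_rule=lambda t: 1.0)
        assert cells1.cells["detected"].all()

    def test_cells_on_grid_and_non_overlapping(self):
        truth = self._truth(200)
        cells = generate_survey_cells(truth.suitability, n_cells=10, seed=3)
        df = cells.cells
        assert (df[["x_min", "y_min"]].to_numpy() % 50 == 0).all()
        assert not df.duplicated(["x_min", "y_min"]).any()

    def test_detected_cells_have_higher_truth(self):
        # spatially coherent truth so 50-m cell means actually vary
        dem = generate_dem(LandscapeConfig(extent=(0, 0, 500, 500), seed=9))
        truth = define_true_suitability({"elevation": dem},
                                        {"elevation": -3.0}, 0.0)
        cells = generate_survey_cells(truth.suitability, n_cells=60, seed=9,
                                      cell_size_m=50.0)
        df = cells.cells
        det = df[df["detected"]]["truth_mean"]
        und = df[~df["detected"]]["truth_mean"]
        assert len(det) and len(und)
        assert det.mean() > und.mean()

    def test_misaligned_cell_size_rejected(self):
        truth = self._truth()
        with pytest.raises(ValueError):
            generate_survey_cells(truth.suitability, n_cells=2, seed=0,
                                  cell_size_m=33.3)
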