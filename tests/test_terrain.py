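import numpy as np
import pandas as pd
import pytest

from conftest import make_plane
from habsuit import (CovariateStack, GridRaster, aspect_components,
                     compute_slope, extract_covariates,
                     geology_distance_classes, resample_bilinear,
                     soil_color_index)


class TestSlope:
    def test_flat_dem_zero_slope(self, flat_raster):
        assert np.allclose(compute_slope(flat_raster).values, 0.0)

    @pytest.mark.parametrize("grad,expected_deg", [
        (1.0, 45.0),
        (0.5, np.degrees(np.arctan(0.5))),
    ])
    def test_plane_slope_closed_form(self, grad, expected_deg):
        dem = make_plane(slope_x=grad)
        slope = compute_slope(dem)
        interior = slope.values[1:-1, 1:-1]
        assert np.allclose(interior, expected_deg, atol=1e-9)

    def test_tiny_raster_rejected(self):
        with pytest.raises(ValueError):
            compute_slope(GridRaster(np.zeros((2, 2)), 0, 0, 1.0))


class TestAspect:
    @pytest.mark.parametrize("sx,sy,n_exp,e_exp", [
        (0.0, -1.0, 1.0, 0.0),   # z rises south -> faces north (aspect 0)
        (0.0, 1.0, -1.0, 0.0),   # z rises north -> faces south (aspect 180)
        (-1.0, 0.0, 0.0, 1.0),   # z rises west -> faces east (aspect 90)
        (1.0, 0.0, 0.0, -1.0),   # faces west (aspect 270)
    ])
    def test_cardinal_aspects(self, sx, sy, n_exp, e_exp):
        dem = make_plane(slope_x=sx, slope_y=sy)
        northness, eastness = aspect_components(dem)
        assert np.allclose(northness.values[1:-1, 1:-1], n_exp, atol=1e-12)
        assert np.allclose(eastness.values[1:-1, 1:-1], e_exp, atol=1e-12)

    def test_unit_circle_on_sloped_cells_zero_on_flats(self):
        rng = np.random.default_rng(8)
        dem = GridRaster(rng.normal(size=(12, 12)), 0, 0, 1.0)
        n, e = aspect_components(dem)
        norm = n.values ** 2 + e.values ** 2
        assert np.allclose(norm, 1.0, atol=1e-12)
        flat = make_plane(0.0, 0.0)
        nf, ef = aspect_components(flat)
        assert np.all(nf.values == 0.0) and np.all(ef.values == 0.0)


class TestGeologyClasses:
    def test_interval_membership(self):
        mask = GridRaster(np.zeros((30, 30)), 0, 0, 1.0)
        vals = mask.values.copy()
        vals[15, 15] = 1.0
        classes = geology_distance_classes(mask.like(vals))
        assert classes.values[15, 15] == 1  # inside the formation
        assert classes.values[15, 20] == 2  # 5 m away
        assert classes.values[15, 26] == 3  # 11 m away
        far = GridRaster(np.zeros((3, 150)), 0, 0, 1.0)
        fv = far.values.copy()
        fv[1, 0] = 1.0
        far_classes = geology_distance_classes(far.like(fv))
        assert far_classes.values[1, 120] == 4  # 120 m -> class 4

    def test_seven_cells_away_is_class_two(self):
        mask = GridRaster(np.zeros((20, 20)), 0, 0, 1.0)
        vals = mask.values.copy()
        vals[0, 0] = 1.0
        classes = geology_distance_classes(mask.like(vals))
        assert classes.values[0, 7] == 2.0

    def test_matches_bruteforce_nearest_cell_search(self):
        rng = np.random.default_rng(12)
        mask_vals = (rng.uniform(size=(25, 25)) < 0.05).astype(float)
        mask_vals[3, 4] = 1.0  # ensure non-empty
        mask = GridRaster(mask_vals, 0, 0, 2.0)  # 2-m cells
        classes = geology_distance_classes(mask)
        xs, ys = mask.cell_centers()
        form = np.argwhere(mask_vals > 0.5)
        fx = xs[form[:, 1]]
        fy = ys[form[:, 0]]
        edges = np.array([1.0, 10.0, 100.0])
        for r in range(25):
            for c in range(25):
                d = np.min(np.hypot(xs[c] - fx, ys[r] - fy))
                expected = 1 + np.digitize(d, edges)
                assert classes.values[r, c] == expected

    def test_empty_formation_rejected(self, flat_raster):
        with pytest.raises(ValueError):
            geology_distance_classes(flat_raster)


class TestSoilColorIndex:
    def test_arithmetic_and_boundaries(self, flat_raster):
        red = flat_raster.like(np.full((20, 20), 0.3))
        green = flat_raster.like(np.full((20, 20), 0.1))
        idx = soil_color_index(red, green)
        assert np.allclose(idx.values, 0.5)
        equal = soil_color_index(red, red)
        assert np.allclose(equal.values, 0.0)
        zero_green = soil_color_index(red, flat_raster.like(np.zeros((20, 20))))
        assert np.allclose(zero_green.values, 1.0)

    def test_zero_denominator_is_nodata(self, flat_raster):
        zero = flat_raster.like(np.zeros((20, 20)))
        idx = soil_color_index(zero, zero)
        assert np.isnan(idx.values).all()

    def test_misaligned_rejected(self, flat_raster):
        other = GridRaster(np.zeros((20, 20)), 5.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            soil_color_index(flat_raster, other)


class TestBilinearResample:
    def test_constant_in_constant_out(self):
        coarse = GridRaster(np.full((4, 4), 7.0), -10, -10, 10.0)
        target = GridRaster(np.zeros((20, 20)), 0, 0, 1.0)
        fine = resample_bilinear(coarse, target)
        assert np.allclose(fine.values, 7.0)

    def test_center_of_four_cells_is_mean(self):
        coarse = GridRaster(np.array([[0.0, 0.0], [10.0, 10.0]]), 0, 0, 10.0)
        # a 1-cell target whose center (10, 10) is the center of 4 coarse cells
        target = GridRaster(np.zeros((1, 1)), 9.5, 9.5, 1.0)
        fine = resample_bilinear(coarse, target)
        assert np.allclose(fine.values, 5.0)

    def test_exact_at_coarse_centers(self):
        rng = np.random.default_rng(1)
        coarse = GridRaster(rng.normal(size=(5, 5)), 0, 0, 10.0)
        # one fine cell centered exactly on coarse cell (2, 3): (35, 25)
        target = GridRaster(np.zeros((1, 1)), 34.5, 24.5, 1.0)
        fine = resample_bilinear(coarse, target)
        assert np.allclose(fine.values[0, 0], coarse.values[2, 3])

    def test_exact_on_affine_surface(self):
        xs = np.arange(5) * 10 + 5.0
        ys = (np.arange(5) * 10 + 5.0)[::-1]
        plane = 2.0 * xs[None, :] + 3.0 * ys[:, None] + 1.0
        coarse = GridRaster(plane, 0, 0, 10.0)
        target = GridRaster(np.zeros((30, 30)), 10, 10, 1.0)
        fine = resample_bilinear(coarse, target)
        txs, tys = target.cell_centers()
        expected = 2.0 * txs[None, :] + 3.0 * tys[:, None] + 1.0
        assert np.allclose(fine.values, expected)

    def test_uncovered_target_rejected(self):
        coarse = GridRaster(np.zeros((2, 2)), 0, 0, 10.0)
        target = GridRaster(np.zeros((5, 5)), 19, 0, 1.0)
        with pytest.raises(ValueError):
            resample_bilinear(coarse, target)


class TestExtraction:
    def _stack(self):
        rng = np.random.default_rng(2)
        a = GridRaster(rng.normal(size=(10, 10)), 0, 0, 1.0, "a")
        b_vals = rng.normal(size=(10, 10))
        b_vals[0, 0] = np.nan
        b = a.like(b_vals, "b")
        return CovariateStack({"a": a, "b": b}, ["a", "b"])

    def test_point_at_cell_center_gets_cell_values(self):
        stack = self._stack()
        pts = pd.DataFrame({"x": [4.5], "y": [2.5]})
        table, dropped = extract_covariates(pts, stack)
        r, c = stack.template.index_of(4.5, 2.5)
        assert table["a"].iloc[0] == stack["a"].values[r, c]
        assert table["b"].iloc[0] == stack["b"].values[r, c]
        assert len(dropped) == 0

    def test_nodata_point_dropped_with_reason(self):
        stack = self._stack()
        pts = pd.DataFrame({"x": [0.5, 5.0], "y": [9.5, 5.0]})  # first on NaN b
        table, dropped = extract_covariates(pts, stack)
        assert len(table) == 1
        assert len(dropped) == 1
        assert dropped["reason"].iloc[0] == "nodata_cell"

    def test_categorical_geology_expansion(self):
        mask_vals = np.zeros((10, 10))
        mask_vals[0, 0] = 1.0
        mask = GridRaster(mask_vals, 0, 0, 1.0, "formation")
        geo = geology_distance_classes(mask)
        stack = CovariateStack({"geology_class": geo}, ["geology_class"])
        pts = pd.DataFrame({"x": [0.5, 5.5], "y": [9.5, 9.5]})
        table, _ = extract_covariates(pts, stack, categorical_geology=True)
        assert "geology_class" not in table
        cols = [f"geology_class_{k}" for k in (1, 2, 3, 4)]
        assert table[cols].to_numpy().sum(axis=1).tolist() == [1.0, 1.0]
        assert table["geology_class_1"].iloc[0] == 1.0
        assert table["geology_class_2"].iloc[1] == 1.0

    def test_bookkeeping_identity(self):
        stack = self._stack()
        rng = np.random.default_rng(9)
        pts = pd.DataFrame({"x": rng.uniform(-2, 12, 100),
                            "y": rng.uniform(-2, 12, 100)})
        table, dropped = extract_covariates(pts, stack)
        assert len(table) + len(dropped) == 100
        assert set(dropped["reason"]) <= {"outside_extent", "nodata_cell"}
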