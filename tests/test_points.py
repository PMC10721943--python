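import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import Polygon, box

from habsuit import (GridRaster, SplitSpec, absence_from_survey,
                     assemble_presences, exclusion_filter, generate_background,
                     polygon_to_points, split_train_validation, thin_points)
from habsuit.points import make_points
from habsuit.survey import SurveyCellSet


def greedy_thin_oracle(xy, min_dist):
    kept = []
    for i, p in enumerate(xy):
        if all(np.hypot(p[0] - xy[j][0], p[1] - xy[j][1]) >= min_dist
               for j in kept):
            kept.append(i)
    return kept


class TestThinning:
    def test_collinear_example(self):
        pts = make_points([0.0, 1.0, 2.0, 3.0], [0.0] * 4, "presence",
                          "point_obs")
        out = thin_points(pts, 2.0)
        assert list(out["x"]) == [0.0, 2.0]

    def test_zero_distance_is_identity(self):
        pts = make_points([0.0, 0.1], [0.0, 0.0], "presence", "point_obs")
        out = thin_points(pts, 0.0)
        assert len(out) == 2

    def test_coincident_points_keep_one(self):
        pts = make_points([1.0] * 10, [1.0] * 10, "presence", "point_obs")
        assert len(thin_points(pts, 2.0)) == 1

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=0, max_size=200),
           st.floats(0.1, 30.0))
    def test_matches_bruteforce_greedy_oracle(self, coords, min_dist):
        xy = np.array(coords).reshape(-1, 2)
        pts = make_points(xy[:, 0], xy[:, 1], "presence", "point_obs")
        out = thin_points(pts, min_dist)
        expected = greedy_thin_oracle(xy, min_dist)
        assert list(out.index) == list(range(len(expected)))
        np.testing.assert_array_equal(out[["x", "y"]].to_numpy(), xy[expected])
        # pairwise distances all >= min_dist
        kept = out[["x", "y"]].to_numpy()
        for i in range(len(kept)):
            for j in range(i + 1, len(kept)):
                assert np.hypot(*(kept[i] - kept[j])) >= min_dist - 1e-9


class TestPolygonToPoints:
    def test_small_polygon_yields_centroid(self):
        rect = box(0, 0, 3, 5)  # 15 m^2 < 20 m^2
        pts, errors = polygon_to_points([rect])
        assert len(pts) == 1 and not errors
        assert pts["x"].iloc[0] == 1.5 and pts["y"].iloc[0] == 2.5

    def test_square_30m_thins_to_single_point(self):
        square = box(0, 0, 30, 30)
        # 9 grid centroids, all within sqrt(800) < 40 m of each other
        pts, _ = polygon_to_points([square])
        assert len(pts) == 1

    def test_strip_10_by_90_keeps_three(self):
        strip = box(0, 0, 10, 90)
        pts, _ = polygon_to_points([strip])
        assert len(pts) == 3
        assert sorted(pts["y"]) == [5.0, 45.0, 85.0]

    def test_sliver_falls_back_to_centroid(self):
        # 100 m x 0.3 m = 30 m^2 >= 20 but covers no 10-m cell center
        sliver = box(0, 3.0, 100, 3.3)
        pts, _ = polygon_to_points([sliver])
        assert len(pts) == 1

    def test_invalid_geometry_recorded_and_skipped(self):
        bowtie = Polygon([(0, 0), (2, 2), (2, 0), (0, 2)])
        ok = box(0, 0, 3, 5)
        pts, errors = polygon_to_points([bowtie, ok])
        assert len(errors) == 1 and errors[0]["polygon_index"] == 0
        assert len(pts) == 1


class TestBackground:
    def _mask(self, shape=(30, 30)):
        return GridRaster(np.ones(shape), 0, 0, 1.0)

    def test_exact_count_returned(self):
        out = generate_background(self._mask(), 1234, seed=0)
        assert len(out) == 1234

    def test_single_valid_cell_confines_points(self):
        vals = np.zeros((10, 10))
        vals[4, 7] = 1.0
        out = generate_background(GridRaster(vals, 0, 0, 1.0), 50, seed=1)
        assert ((out["x"] >= 7.0) & (out["x"] <= 8.0)).all()
        assert ((out["y"] >= 5.0) & (out["y"] <= 6.0)).all()

    def test_uniformity_quadrat_chi_square(self):
        from scipy import stats
        out = generate_background(self._mask((100, 100)), 5000, seed=7)
        counts, _, _ = np.histogram2d(out["x"], out["y"], bins=5,
                                      range=[[0, 100], [0, 100]])
        stat = ((counts - 200.0) ** 2 / 200.0).sum()
        assert stats.chi2.sf(stat, df=24) > 0.01


class TestAbsences:
    def test_undetected_100m_cell_yields_25_points(self):
        cells = SurveyCellSet.from_arrays([0.0], [0.0], 100.0, [False])
        pts = absence_from_survey(cells, grid_m=20.0)
        assert len(pts) == 25

    def test_fully_detected_cell_yields_none(self):
        cells = SurveyCellSet.from_arrays([0.0], [0.0], 100.0, [True])
        assert len(absence_from_survey(cells)) == 0

    def test_detection_strip_removes_one_row(self):
        pts = absence_from_survey([box(0, 0, 100, 100)],
                                  detection_areas=[box(0, 0, 100, 20)],
                                  grid_m=20.0)
        assert len(pts) == 20


class TestExclusion:
    def _presences(self):
        return make_points([0.0], [0.0], "presence", "point_obs")

    def test_closer_than_radius_removed_tie_kept(self):
        cands = make_points([50.0, 100.0, 150.0], [0.0, 0.0, 0.0],
                            "background", "random_background")
        out = exclusion_filter(cands, self._presences(), 100.0)
        assert sorted(out["x"]) == [100.0, 150.0]

    def test_no_presences_is_identity(self):
        cands = make_points([1.0, 2.0], [0.0, 0.0], "background",
                            "random_background")
        empty = make_points([], [], "presence", "point_obs")
        assert len(exclusion_filter(cands, empty, 100.0)) == 2


class TestAssemblyAndSplit:
    def test_merge_and_count_by_source(self):
        obs = make_points(np.arange(0, 50, 5.0), np.zeros(10), "presence",
                          "point_obs")
        poly = make_points(np.arange(2.5, 52, 5.0), np.full(10, 100.0),
                           "presence", "polygon_derived")
        merged, counts = assemble_presences(obs, poly, thin_m=2.0)
        assert counts == {"point_obs": 10, "polygon_derived": 10}
        assert len(merged) == 20

    def test_duplicate_across_sources_one_survives(self):
        obs = make_points([0.0], [0.0], "presence", "point_obs")
        poly = make_points([0.0], [0.0], "presence", "polygon_derived")
        merged, counts = assemble_presences(obs, poly, thin_m=2.0)
        assert len(merged) == 1 and counts == {"point_obs": 1}

    def test_split_two_thirds_partition(self):
        pts = pd.concat([
            make_points(np.arange(900.0), np.zeros(900), "presence",
                        "point_obs"),
            make_points(np.arange(300.0), np.ones(300), "background",
                        "random_background"),
        ], ignore_index=True)
        spec = SplitSpec(seed=5)
        train, valid = split_train_validation(pts, spec)
        assert (train["label"] == "presence").sum() == 600
        assert (valid["label"] == "presence").sum() == 300
        # partition: disjoint and exhaustive
        key = lambda df: set(zip(df["x"], df["y"], df["label"]))
        assert key(train) | key(valid) == key(pts)
        assert not (key(train) & key(valid))
        # determinism
        train2, valid2 = split_train_validation(pts, spec)
        pd.testing.assert_frame_equal(train, train2)

    def test_split_rejects_tiny_label(self):
        pts = make_points([0.0, 1.0], [0.0, 0.0], "presence", "point_obs")
        with pytest.raises(ValueError):
            split_train_validation(pts, SplitSpec())

    def test_label_source_pairing_enforced(self):
        with pytest.raises(ValueError):
            make_points([0.0], [0.0], "presence", "random_background")
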