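"""Occurrence-point engineering for presence-background modelling.

Builds the presence, background and true-absence point sets that the models
consume. Presences come from field point observations plus points derived
from mapped subpopulation polygons (small polygons contribute their
centroid; large ones are rasterized to a 10-m grid and the covered-cell
centroids thinned to 40 m). Background points are uniform over the valid
predictor area; true absences are 20-m cell centroids of surveyed area
without detections. Distance filters ("no points closer than d") are greedy
sequential scans in input order: strictly-closer points are removed, ties at
exactly d are kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import box, mapping

from .grid import GridRaster

__all__ = [
    "SplitSpec",
    "make_points",
    "thin_points",
    "polygon_to_points",
    "generate_background",
    "absence_from_survey",
    "exclusion_filter",
    "assemble_presences",
    "split_train_validation",
    "points_to_geojson",
]

VALID_LABEL_SOURCE = {
    "presence": {"point_obs", "polygon_derived"},
    "background": {"random_background"},
    "absence": {"survey_absence"},
}

POINT_COLUMNS = ["point_id", "x", "y", "label", "source"]


def make_points(x, y, label: str, source: str,
                start_id: int = 0) -> pd.DataFrame:
    """Labelled point table with the label/source pairing enforced."""
    if source not in VALID_LABEL_SOURCE.get(label, set()):
        raise ValueError(f"source {source!r} not valid for label {label!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return pd.DataFrame({
        "point_id": np.arange(start_id, start_id + x.size),
        "x": x, "y": y, "label": label, "source": source,
    })


def thin_points(points: pd.DataFrame, min_dist_m: float) -> pd.DataFrame:
    """Greedy sequential distance filter.

    Scans points in input order and keeps each one iff it is at least
    ``min_dist_m`` from every already-kept point (strictly closer points
    are dropped; distance exactly ``min_dist_m`` is kept). The output is an
    order-preserving subset whose pairwise distances are all >= min_dist_m.
    """
    if min_dist_m < 0:
        raise ValueError("min_dist_m must be >= 0")
    if min_dist_m == 0 or len(points) == 0:
        return points.copy().reset_index(drop=True)
    xy = points[["x", "y"]].to_numpy(dtype=float)
    kept: list[int] = []
    kept_xy = np.empty((0, 2))
    for i in range(len(points)):
        if kept_xy.size:
            d2 = np.sum((kept_xy - xy[i]) ** 2, axis=1)
            if (d2 < min_dist_m ** 2 - 1e-12).any():
                continue
        kept.append(i)
        kept_xy = np.vstack([kept_xy, xy[i]])
    return points.iloc[kept].reset_index(drop=True)


def _grid_cell_centroids(geometry, grid_m: float) -> np.ndarray:
    """Centers of grid cells (aligned to multiples of grid_m) covered by the
    geometry, a cell being covered iff its center lies inside."""
    x0, y0, x1, y1 = geometry.bounds
    cx0 = np.floor(x0 / grid_m) * grid_m
    cy0 = np.floor(y0 / grid_m) * grid_m
    xs = np.arange(cx0 + grid_m / 2, x1, grid_m)
    ys = np.arange(cy0 + grid_m / 2, y1, grid_m)
    if xs.size == 0 or ys.size == 0:
        return np.empty((0, 2))
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(geometry, xx.ravel(), yy.ravel())
    return np.column_stack([xx.ravel()[inside], yy.ravel()[inside]])


def polygon_to_points(polygons, small_area_m2: float = 20.0,
                      grid_m: float = 10.0, thin_m: float = 40.0):
    """Presence points from mapped subpopulation polygons.

    Polygons smaller than ``small_area_m2`` contribute exactly their
    centroid. Larger polygons are rasterized on a ``grid_m`` grid (cell
    covered iff its center falls inside) and contribute one point per
    covered cell; slivers covering no cell center fall back to the centroid
    so every polygon yields at least one candidate. The combined
    polygon-derived candidates are then greedily thinned to pairwise
    distances >= ``thin_m``.

    Returns (points, errors): a presence table with source
    "polygon_derived", and a list of per-polygon error records for invalid
    geometries (which are skipped).
    """
    candidates = []
    errors = []
    for i, poly in enumerate(polygons):
        if poly is None or poly.is_empty or not poly.is_valid:
            errors.append({"polygon_index": i, "error": "invalid or empty geometry"})
            continue
        if poly.area < small_area_m2:
            c = poly.centroid
            candidates.append((c.x, c.y))
        else:
            cells = _grid_cell_centroids(poly, grid_m)
            if cells.shape[0] == 0:
                c = poly.centroid
                candidates.append((c.x, c.y))
            else:
                candidates.extend(map(tuple, cells))
    if candidates:
        xy = np.asarray(candidates)
        pts = make_points(xy[:, 0], xy[:, 1], "presence", "polygon_derived")
        pts = thin_points(pts, thin_m)
        pts["point_id"] = np.arange(len(pts))
    else:
        pts = make_points(np.empty(0), np.empty(0), "presence", "polygon_derived")
    return pts, errors


def generate_background(valid_mask: GridRaster, n: int, seed: int,
                        density_cap_per_km2: float | None = None) -> pd.DataFrame:
    """``n`` background points uniform over the valid (non-nodata) area.

    Cells are drawn uniformly among valid cells and positions jittered
    uniformly within each cell, giving a uniform density over the valid
    area. A configured density cap only warns (the study used very dense
    background, ~43k points).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = np.isfinite(valid_mask.values) & (valid_mask.values > 0.5) \
        if set(np.unique(valid_mask.values[np.isfinite(valid_mask.values)])) <= {0.0, 1.0} \
        else np.isfinite(valid_mask.values)
    if not valid.any():
        raise ValueError("mask has no valid cells")
    if density_cap_per_km2 is not None:
        area_km2 = valid.sum() * valid_mask.cell_size ** 2 / 1e6
        if n > density_cap_per_km2 * area_km2:
            import warnings
            warnings.warn("requested background density exceeds the configured cap",
                          stacklevel=2)
    rng = np.random.default_rng(seed)
    flat = np.flatnonzero(valid.ravel())
    idx = rng.choice(flat, size=n, replace=True)
    r, c = np.unravel_index(idx, valid.shape)
    xs, ys = valid_mask.cell_centers()
    cs = valid_mask.cell_size
    x = xs[c] + rng.uniform(-0.5, 0.5, size=n) * cs
    y = ys[r] + rng.uniform(-0.5, 0.5, size=n) * cs
    return make_points(x, y, "background", "random_background")


def absence_from_survey(survey_cells, detection_areas=None,
                        grid_m: float = 20.0) -> pd.DataFrame:
    """True-absence points from surveyed area without detections.

    ``survey_cells`` is an iterable of shapely polygons (the surveyed
    squares) or a SurveyCellSet, in which case only undetected cells enter.
    Detected areas are masked out, the remainder rasterized at ``grid_m``
    resolution, and one point generated at the centroid of each covered
    cell (cell covered iff its center lies in the remaining area).
    """
    geoms = []
    if hasattr(survey_cells, "cells"):  # SurveyCellSet
        size = survey_cells.size_m
        for rec in survey_cells.cells.itertuples(index=False):
            if not rec.detected:
                geoms.append(box(rec.x_min, rec.y_min,
                                 rec.x_min + size, rec.y_min + size))
    else:
        geoms = [g for g in survey_cells if g is not None and not g.is_empty]
    if not geoms:
        return make_points(np.empty(0), np.empty(0), "absence", "survey_absence")
    surveyed = shapely.union_all(geoms)
    if detection_areas:
        detected = shapely.union_all(list(detection_areas))
        surveyed = surveyed.difference(detected)
    if surveyed.is_empty:
        return make_points(np.empty(0), np.empty(0), "absence", "survey_absence")
    xy = _grid_cell_centroids(surveyed, grid_m)
    return make_points(xy[:, 0], xy[:, 1], "absence", "survey_absence")


def exclusion_filter(candidates: pd.DataFrame, presences: pd.DataFrame,
                     radius_m: float = 100.0) -> pd.DataFrame:
    """Drop candidates strictly closer than ``radius_m`` to any presence.

    Distance exactly ``radius_m`` is kept ("closer than" removes strict
    inequality only).
    """
    if radius_m < 0:
        raise ValueError("radius_m must be >= 0")
    if len(presences) == 0 or len(candidates) == 0 or radius_m == 0:
        return candidates.copy().reset_index(drop=True)
    tree = cKDTree(presences[["x", "y"]].to_numpy(dtype=float))
    d, _ = tree.query(candidates[["x", "y"]].to_numpy(dtype=float))
    keep = d >= radius_m - 1e-9
    return candidates[keep].reset_index(drop=True)


def assemble_presences(point_obs: pd.DataFrame, polygon_points: pd.DataFrame,
                       thin_m: float = 2.0):
    """Merge point observations with polygon-derived points, 2-m thin, and
    report surviving counts by source.

    Returns (presences, counts_by_source).
    """
    merged = pd.concat([point_obs, polygon_points], ignore_index=True)
    thinned = thin_points(merged, thin_m)
    thinned["point_id"] = np.arange(len(thinned))
    counts = thinned["source"].value_counts().to_dict()
    return thinned, counts


@dataclass
class SplitSpec:
    """Per-label random train/validation split (default two-thirds train)."""

    train_fraction: float = 2.0 / 3.0
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")


def split_train_validation(points: pd.DataFrame, spec: SplitSpec):
    """Disjoint, exhaustive, per-label random split.

    Each label's point count is split at ``train_fraction`` (rounded to
    nearest, at least one point on each side); labels with fewer than three
    points are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    groups = [("all", points)] if not spec.stratified else [
        (lbl, grp) for lbl, grp in points.groupby("label", sort=True)
    ]
    train_parts, valid_parts = [], []
    for lbl, grp in groups:
        n = len(grp)
        if n < 3:
            raise ValueError(f"label {lbl!r} has fewer than 3 points")
        n_train = int(round(n * spec.train_fraction))
        n_train = min(max(n_train, 1), n - 1)
        perm = rng.permutation(n)
        train_parts.append(grp.iloc[perm[:n_train]])
        valid_parts.append(grp.iloc[perm[n_train:]])
    train = pd.concat(train_parts, ignore_index=True)
    valid = pd.concat(valid_parts, ignore_index=True)
    return train, valid


def points_to_geojson(points: pd.DataFrame, path) -> None:
    """Write a point table as a GeoJSON FeatureCollection."""
    features = []
    for rec in points.itertuples(index=False):
        props = {k: getattr(rec, k) for k in points.columns if k not in ("x", "y")}
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [rec.x, rec.y]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def geometry_to_geojson(geometries, path) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": {"id": i}}
        for i, g in enumerate(geometries)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
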