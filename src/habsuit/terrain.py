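"""Terrain and spectral covariates on an aligned grid stack.

Slope and aspect come from Horn's 3x3 finite differences on the DEM (the
stencil used by most GIS packages), with edge replication at the border.
Aspect — the compass direction a cell faces downhill, degrees clockwise from
north — is circular, so it enters models only through its linearizing
components northness = cos(aspect·π/180) and eastness = sin(aspect·π/180).
Proximity to the target geologic formation is carried as four ordinal
distance classes (within/1 m, 1–10 m, 10–100 m, >100 m), and bare-soil
color as the spectral index (Red − Green)/(Red + Green).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import distance_transform_edt

from .grid import GridRaster

__all__ = [
    "CovariateStack",
    "compute_slope",
    "aspect_components",
    "geology_distance_classes",
    "soil_color_index",
    "resample_bilinear",
    "extract_covariates",
]

GEOLOGY_CLASS_EDGES = (1.0, 10.0, 100.0)  # meters; class 1 = within/<1 m


def _horn_gradients(dem: GridRaster) -> tuple[np.ndarray, np.ndarray]:
    """(dz/dx eastward, dz/dy northward) by Horn's stencil, edge-replicated."""
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3")
    z = np.pad(dem.values, 1, mode="edge")
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    cs = dem.cell_size
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    # row index grows southward, so the northward derivative flips sign
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)
    return dzdx, dzdy


def compute_slope(dem: GridRaster) -> GridRaster:
    """Slope in degrees: arctan of the Horn gradient magnitude."""
    dzdx, dzdy = _horn_gradients(dem)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[np.isnan(dem.values)] = np.nan
    return dem.like(slope, "slope")


def aspect_components(dem: GridRaster) -> tuple[GridRaster, GridRaster]:
    """Northness and eastness of the downhill direction.

    Aspect is measured clockwise from north toward the downslope direction
    (−∇z). Flat cells, where aspect is undefined, get both components 0 so
    they contribute no directional signal.
    """
    dzdx, dzdy = _horn_gradients(dem)
    flat = (dzdx == 0) & (dzdy == 0)
    aspect = np.arctan2(-dzdx, -dzdy)  # radians clockwise from north
    northness = np.where(flat, 0.0, np.cos(aspect))
    eastness = np.where(flat, 0.0, np.sin(aspect))
    nan = np.isnan(dem.values)
    northness[nan] = np.nan
    eastness[nan] = np.nan
    return dem.like(northness, "northness"), dem.like(eastness, "eastness")


def geology_distance_classes(formation_mask: GridRaster) -> GridRaster:
    """Ordinal distance-to-formation classes 1–4.

    Euclidean distance from each cell center to the nearest formation cell
    center (0 inside the formation), binned at 1 m, 10 m and 100 m.
    """
    mask = formation_mask.values > 0.5
    if not mask.any():
        raise ValueError("formation mask has no formation cells")
    dist = distance_transform_edt(~mask, sampling=formation_mask.cell_size)
    classes = 1.0 + np.digitize(dist, GEOLOGY_CLASS_EDGES)
    classes[np.isnan(formation_mask.values)] = np.nan
    return formation_mask.like(classes, "geology_class")


def soil_color_index(red: GridRaster, green: GridRaster) -> GridRaster:
    """(Red − Green)/(Red + Green); nodata where the denominator is zero."""
    if not red.aligned_with(green):
        raise ValueError("red and green grids are not aligned")
    r = red.values
    g = green.values
    denom = r + g
    with np.errstate(invalid="ignore", divide="ignore"):
        idx = np.where(denom > 0, (r - g) / denom, np.nan)
    return red.like(idx, "soil_color_index")


def resample_bilinear(coarse: GridRaster, target: GridRaster) -> GridRaster:
    """Bilinear interpolation of a coarse raster onto a fine target grid.

    Interpolates between the four nearest coarse cell centers at each target
    cell center; beyond the hull of coarse centers (but inside the coarse
    footprint) edge values are extended. The coarse raster must cover the
    target extent.
    """
    if (coarse.x_min > target.x_min or coarse.y_min > target.y_min
            or coarse.x_max < target.x_max or coarse.y_max < target.y_max):
        raise ValueError("coarse raster does not cover the target extent")
    cx, cy = coarse.cell_centers()
    tx, ty = target.cell_centers()
    # clamp to the coarse center hull = edge extension outside it
    qx = np.clip(tx, cx[0], cx[-1])
    qy = np.clip(ty, cy[-1], cy[0])
    interp = RegularGridInterpolator(
        (cy[::-1], cx), coarse.values[::-1, :], method="linear",
        bounds_error=True,
    )
    yy, xx = np.meshgrid(qy, qx, indexing="ij")
    fine = interp(np.column_stack([yy.ravel(), xx.ravel()]))
    return target.like(fine.reshape(target.values.shape), coarse.name)


@dataclass
class CovariateStack:
    """Aligned named covariate layers sharing one grid."""

    layers: dict[str, GridRaster]
    layer_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        if not self.layer_names:
            self.layer_names = list(self.layers)
        template = self.layers[self.layer_names[0]]
        for name in self.layer_names:
            if name not in self.layers:
                raise ValueError(f"layer {name!r} missing from stack")
            if not self.layers[name].aligned_with(template):
                raise ValueError(f"layer {name!r} is not aligned with the stack")

    @property
    def template(self) -> GridRaster:
        return self.layers[self.layer_names[0]]

    def __getitem__(self, name: str) -> GridRaster:
        return self.layers[name]

    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.template.values.shape, dtype=bool)
        for name in self.layer_names:
            mask &= np.isfinite(self.layers[name].values)
        return mask

    def as_table(self) -> pd.DataFrame:
        """All valid cells as rows (with row/col indices), one column per layer."""
        mask = self.valid_mask()
        rows, cols = np.nonzero(mask)
        data = {"row": rows, "col": cols}
        for name in self.layer_names:
            data[name] = self.layers[name].values[rows, cols]
        return pd.DataFrame(data)

    def write(self, directory, manifest: str = "stack.yaml") -> None:
        import pathlib
        import yaml

        directory = pathlib.Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = {}
        for name in self.layer_names:
            path = directory / f"{name}.asc"
            self.layers[name].write_ascii_grid(path)
            entries[name] = path.name
        with open(directory / manifest, "w") as fh:
            yaml.safe_dump({"layers": entries}, fh)

    @classmethod
    def read(cls, directory, manifest: str = "stack.yaml") -> "CovariateStack":
        import pathlib
        import yaml

        from .grid import read_ascii_grid

        directory = pathlib.Path(directory)
        with open(directory / manifest) as fh:
            entries = yaml.safe_load(fh)["layers"]
        layers = {
            name: read_ascii_grid(directory / fname, name)
            for name, fname in entries.items()
        }
        return cls(layers, list(entries))


def extract_covariates(points: pd.DataFrame, stack: CovariateStack,
                       categorical_geology: bool = False):
    """Containing-cell covariate lookup at point locations.

    ``points`` needs columns x and y (any others, e.g. point_id/label, are
    carried through). Points outside the stack extent or landing on a nodata
    cell in any layer are excluded from the returned table and reported in
    the companion drop record with a reason.

    By default the ordinal geology_class layer stays a single numeric
    column; ``categorical_geology`` expands it into one indicator column per
    class (geology_class_1 .. geology_class_4) instead.

    Returns (table, dropped) where ``table`` has one covariate column per
    stack layer and ``dropped`` has columns of the input plus ``reason``.
    """
    template = stack.template
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    inside = template.contains(x, y)
    out = points.copy().reset_index(drop=True)
    values = {}
    nodata_hit = np.zeros(len(out), dtype=bool)
    for name in stack.layer_names:
        v = stack.layers[name].value_at(x, y)
        values[name] = v
        nodata_hit |= inside & ~np.isfinite(v)
    for name, v in values.items():
        out[name] = v
    reason = np.where(~inside, "outside_extent",
                      np.where(nodata_hit, "nodata_cell", ""))
    keep = inside & ~nodata_hit
    dropped = out[~keep].copy()
    dropped["reason"] = reason[~keep]
    out = out[keep].reset_index(drop=True)
    if categorical_geology and "geology_class" in out:
        for klass in (1, 2, 3, 4):
            out[f"geology_class_{klass}"] = (
                out["geology_class"] == klass).astype(float)
        out = out.drop(columns="geology_class")
    return out, dropped.reset_index(drop=True)
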