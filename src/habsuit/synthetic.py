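"""Synthetic landscapes with known truth.

Everything downstream of raw data — terrain derivatives, occurrence
engineering, model fitting, ensembling, thresholding, survey validation —
is exercised here against a virtual species: a logistic suitability surface
over generated covariates. The generators emulate the shape of the study
system (a 1-m DEM over shale badlands, a coarse 800-m north–south
precipitation gradient, a minority geologic formation whose soil is
spectrally distinct, point and polygon occurrences, 50-m survey cells) while
keeping the true habitat function known, so recovery is testable.

All randomness flows from one master seed split into named substreams
(dem, geology, bands, species, survey): regenerating one layer never
perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit
import shapely
from shapely.geometry import LineString, Point, box

from .grid import GridRaster
from .survey import SurveyCellSet

__all__ = [
    "LandscapeConfig",
    "TruthModel",
    "generate_dem",
    "generate_geology",
    "generate_precipitation",
    "generate_spectral_bands",
    "define_true_suitability",
    "sample_virtual_species",
    "generate_survey_cells",
    "substream",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child stream of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass
class LandscapeConfig:
    """Geometry and texture of the synthetic study area.

    extent is (x_min, y_min, x_max, y_max) in projected meters; width and
    height must be positive integer multiples of ``cell_size_m``.
    ``relief_amplitude_m`` is the standard deviation of elevation around its
    trend; ``roughness`` controls spatial grain (higher = shorter
    correlation length). ``formation_fraction`` is the share of the extent
    the target geologic formation should occupy.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 300.0, 300.0)
    cell_size_m: float = 1.0
    precip_cell_size_m: float = 800.0
    relief_amplitude_m: float = 5.0
    roughness: float = 1.0
    formation_fraction: float = 0.3
    seed: int = 0
    base_elevation_m: float = 1600.0
    trend_north_m_per_m: float = 0.0

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if self.cell_size_m <= 0 or self.precip_cell_size_m <= 0:
            raise ValueError("cell sizes must be positive")
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent must have positive width and height")
        if self.precip_cell_size_m < self.cell_size_m:
            raise ValueError("precip_cell_size_m must be >= cell_size_m")
        if not (0.0 < self.formation_fraction < 1.0):
            raise ValueError("formation_fraction must be in (0, 1)")
        if self.relief_amplitude_m < 0 or self.roughness < 0:
            raise ValueError("relief_amplitude_m and roughness must be >= 0")
        for length, name in ((x1 - x0, "width"), (y1 - y0, "height")):
            n = length / self.cell_size_m
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"extent {name} must be a multiple of cell_size_m")

    @property
    def nrows(self) -> int:
        return round((self.extent[3] - self.extent[1]) / self.cell_size_m)

    @property
    def ncols(self) -> int:
        return round((self.extent[2] - self.extent[0]) / self.cell_size_m)

    def empty_grid(self, name: str = "layer") -> GridRaster:
        return GridRaster(
            np.zeros((self.nrows, self.ncols)),
            self.extent[0], self.extent[1], self.cell_size_m, name,
        )


@dataclass
class TruthModel:
    """Known logistic habitat function of a virtual species."""

    coefficients: dict[str, float]
    intercept: float
    suitability: GridRaster = field(repr=False)


def generate_dem(config: LandscapeConfig) -> GridRaster:
    """Smoothed-random-field DEM with optional planar trend.

    Low-pass-filtered white noise scaled to ``relief_amplitude_m`` standard
    deviation; the Gaussian smoothing length shrinks as ``roughness`` grows,
    so lower roughness means longer-range autocorrelation.
    """
    rng = substream(config.seed, "dem")
    grid = config.empty_grid("elevation")
    _, ys = grid.cell_centers()
    trend = config.base_elevation_m + config.trend_north_m_per_m * ys[:, None]
    values = np.broadcast_to(trend, (config.nrows, config.ncols)).copy()
    if config.relief_amplitude_m > 0:
        noise = rng.standard_normal((config.nrows, config.ncols))
        if config.roughness > 0:
            sigma = 8.0 / config.roughness
            noise = gaussian_filter(noise, sigma=sigma, mode="reflect")
        sd = noise.std()
        if sd > 0:
            noise = noise / sd
        values = values + config.relief_amplitude_m * noise
    return grid.like(values, "elevation")


def _blob(rng: np.random.Generator, config: LandscapeConfig,
          radius: float, n_steps: int = 12):
    """One buffered-random-walk blob clipped to the extent."""
    x0, y0, x1, y1 = config.extent
    start = np.array([rng.uniform(x0, x1), rng.uniform(y0, y1)])
    steps = rng.normal(scale=radius, size=(n_steps, 2))
    path = start + np.cumsum(steps, axis=0)
    line = LineString(np.vstack([start, path]))
    blob = line.buffer(radius)
    return blob.intersection(box(x0, y0, x1, y1))


def generate_geology(config: LandscapeConfig):
    """Formation polygons plus the matching binary cell-center mask.

    Blobs (buffered random walks) accumulate until the masked-cell share
    reaches ``formation_fraction``; each blob is small relative to the
    target so the final share stays within ±20 % of it. The mask is defined
    as cell centers covered by the polygon union, so vector and raster views
    are consistent by construction.
    """
    rng = substream(config.seed, "geology")
    grid = config.empty_grid("formation")
    xs, ys = grid.cell_centers()
    xx, yy = np.meshgrid(xs, ys)
    area = (config.extent[2] - config.extent[0]) * (config.extent[3] - config.extent[1])
    target_blob_area = 0.10 * config.formation_fraction * area
    # buffered walk area is roughly (walk length)·2r ≈ 12·r·2r
    radius = max(config.cell_size_m, np.sqrt(target_blob_area / 24.0))
    polygons = []
    mask = np.zeros((config.nrows, config.ncols), dtype=bool)
    n_cells = mask.size
    for _ in range(400):
        if mask.sum() / n_cells >= 0.97 * config.formation_fraction:
            break
        blob = _blob(rng, config, radius)
        if blob.is_empty:
            continue
        new = mask | shapely.contains_xy(blob, xx, yy)
        if new.sum() / n_cells > 1.18 * config.formation_fraction:
            continue  # overshoot; try a different blob
        polygons.append(blob)
        mask = new
    mask_grid = grid.like(mask.astype(float), "formation")
    return polygons, mask_grid


def generate_precipitation(config: LandscapeConfig,
                           low: float, high: float) -> GridRaster:
    """Coarse precipitation grid declining from south (``high``) to north.

    Values in mm on a ``precip_cell_size_m`` grid anchored to the extent's
    northwest corner and padded to cover the full extent, as required for
    bilinear resampling back onto the base grid.
    """
    if low >= high:
        raise ValueError("low must be < high")
    x0, y0, x1, y1 = config.extent
    cs = config.precip_cell_size_m
    # pad one coarse cell each way so cell centers bracket the fine extent
    ncols = int(np.ceil((x1 - x0) / cs)) + 2
    nrows = int(np.ceil((y1 - y0) / cs)) + 2
    if nrows < 2:
        nrows = 2
    col_vals = np.linspace(low, high, nrows)  # row 0 = north = low
    values = np.repeat(col_vals[:, None], ncols, axis=1)
    y_min = y1 + cs - nrows * cs
    return GridRaster(values, x0 - cs, y_min, cs, "precipitation")


def generate_spectral_bands(formation_mask: GridRaster, noise_sd: float,
                            seed: int,
                            on_formation: tuple[float, float] = (0.3, 0.1),
                            off_formation: tuple[float, float] = (0.2, 0.2)):
    """Red/green reflectance bands whose soil color index is elevated on
    the formation.

    Defaults give index (R−G)/(R+G) of 0.5 on-formation and 0.0 off at zero
    noise. Gaussian noise of ``noise_sd`` is added per band and reflectances
    floored at a small positive value.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = substream(seed, "bands")
    on = formation_mask.values > 0.5
    red = np.where(on, on_formation[0], off_formation[0]).astype(float)
    green = np.where(on, on_formation[1], off_formation[1]).astype(float)
    if noise_sd > 0:
        red = red + rng.normal(scale=noise_sd, size=red.shape)
        green = green + rng.normal(scale=noise_sd, size=green.shape)
    red = np.clip(red, 1e-6, None)
    green = np.clip(green, 1e-6, None)
    return (formation_mask.like(red, "red"), formation_mask.like(green, "green"))


def define_true_suitability(layers: dict[str, GridRaster],
                            coefficients: dict[str, float],
                            intercept: float) -> TruthModel:
    """Logistic truth: inverse-logit of a linear predictor over standardized
    covariate layers."""
    missing = set(coefficients) - set(layers)
    if missing:
        raise ValueError(f"missing covariate layers: {sorted(missing)}")
    template = next(iter(layers.values()))
    eta = np.full(template.values.shape, float(intercept))
    for name, coef in coefficients.items():
        vals = layers[name].values
        valid = np.isfinite(vals)
        mu = vals[valid].mean() if valid.any() else 0.0
        sd = vals[valid].std() if valid.any() else 0.0
        z = (vals - mu) / sd if sd > 0 else np.zeros_like(vals)
        eta = eta + coef * z
        eta[~valid] = np.nan
    suit = expit(eta)
    return TruthModel(dict(coefficients), float(intercept),
                      template.like(suit, "true_suitability"))


def sample_virtual_species(truth: TruthModel, n_points: int, n_polygons: int,
                           polygon_radius_m: float, seed: int):
    """Presence points and subpopulation polygons drawn from the truth.

    Point locations are cells sampled with probability proportional to true
    suitability, jittered uniformly within the cell. Polygons are buffered
    disks centered on high-suitability sampled cells, standing in for the
    larger, more continuous subpopulations that field observers map as
    polygons rather than points.
    """
    if truth is None or truth.suitability is None:
        raise ValueError("truth model is undefined")
    if n_points < 0 or n_polygons < 0:
        raise ValueError("counts must be >= 0")
    rng = substream(seed, "species")
    suit = truth.suitability
    w = np.nan_to_num(suit.values, nan=0.0).ravel()
    total = w.sum()
    xs, ys = suit.cell_centers()
    cs = suit.cell_size

    def _draw(n: int) -> tuple[np.ndarray, np.ndarray]:
        if n == 0 or total <= 0:
            return np.empty(0), np.empty(0)
        idx = rng.choice(w.size, size=n, replace=True, p=w / total)
        r, c = np.unravel_index(idx, suit.values.shape)
        x = xs[c] + rng.uniform(-0.5, 0.5, size=n) * cs
        y = ys[r] + rng.uniform(-0.5, 0.5, size=n) * cs
        return x, y

    px, py = _draw(n_points)
    points = [Point(x, y) for x, y in zip(px, py)]

    polygons = []
    if n_polygons > 0 and total > 0:
        # restrict polygon seeds to the top-suitability quintile
        thresh = np.quantile(w[w > 0], 0.8) if (w > 0).any() else 0.0
        w_hi = np.where(w >= thresh, w, 0.0)
        if w_hi.sum() <= 0:
            w_hi = w
        idx = rng.choice(w.size, size=n_polygons, replace=False,
                         p=w_hi / w_hi.sum())
        r, c = np.unravel_index(idx, suit.values.shape)
        bbox = box(*suit.extent)
        for x, y in zip(xs[c], ys[r]):
            polygons.append(Point(x, y).buffer(polygon_radius_m).intersection(bbox))
    return points, polygons


def generate_survey_cells(suitability: GridRaster, n_cells: int,
                          seed: int, cell_size_m: float = 50.0,
                          detection_rule=None,
                          placement: str = "random") -> SurveyCellSet:
    """Non-overlapping square survey cells with Bernoulli detections.

    The study protocol records which 50-m cells were walked and whether the
    species was found in each; here detection is drawn from
    ``detection_rule`` (a probability as a function of the cell's mean true
    suitability; default: the suitability itself clipped to [0.01, 0.99], so
    both detections and non-detections occur). ``placement`` is "random"
    (uniform over candidate cells) or "suitability" (weighted toward high
    suitability, emulating surveys that target predicted habitat); the
    study's own placement rule is not documented, so it is a policy knob.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ratio = cell_size_m / suitability.cell_size
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("cell_size_m must be a multiple of the raster cell size")
    k = round(ratio)
    rng = substream(seed, "survey")
    nrows_b = suitability.nrows // k
    ncols_b = suitability.ncols // k
    if nrows_b * ncols_b < n_cells:
        raise ValueError("extent too small for requested number of cells")
    block = suitability.values[: nrows_b * k, : ncols_b * k].reshape(
        nrows_b, k, ncols_b, k
    )
    with np.errstate(invalid="ignore"):
        truth_mean = np.nanmean(block, axis=(1, 3)).ravel()
    candidates = np.flatnonzero(np.isfinite(truth_mean))
    if placement == "suitability":
        p = truth_mean[candidates] + 1e-9
        p = p / p.sum()
        chosen = rng.choice(candidates, size=n_cells, replace=False, p=p)
    elif placement == "random":
        chosen = rng.choice(candidates, size=n_cells, replace=False)
    else:
        raise ValueError(f"unknown placement policy: {placement}")
    chosen = np.sort(chosen)
    br, bc = np.unravel_index(chosen, (nrows_b, ncols_b))
    x_min = suitability.x_min + bc * cell_size_m
    y_min = suitability.y_max - (br + 1) * cell_size_m
    tm = truth_mean[chosen]
    if detection_rule is None:
        prob = np.clip(tm, 0.01, 0.99)
    else:
        prob = np.clip(np.asarray([detection_rule(t) for t in tm], dtype=float),
                       0.0, 1.0)
    detected = rng.uniform(size=n_cells) < prob
    return SurveyCellSet.from_arrays(
        x_min=x_min, y_min=y_min, size_m=cell_size_m,
        detected=detected, truth_mean=tm,
    )
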