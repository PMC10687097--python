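"""Synthetic landscape generator.

Builds fully synthetic stand-ins for the inputs a census-downscaling run
needs: a district (zone) raster, settlement points with heavy-tailed
populations clustered inside districts, annual stacks of 13 spatially
autocorrelated covariate layers, and a latent "true" livestock-density
surface that decays with distance from settlements, responds to the
covariates, and carries an injected linear trend plus noise. District census
tables are then obtained by *exact* aggregation of the truth, so every
downstream stage (sampling, random-forest disaggregation, dasymetric
adjustment, trend detection) can be tested end to end without external data.

The generator mimics the structure the analysis assumes, not the physics of
any real covariate: layers are mutually independent random fields (apart
from the settlement-derived ones) with no seasonal signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridGeometry

logger = logging.getLogger(__name__)

#: Species the census distinguishes.
SPECIES = ("small_ruminant", "horse")

#: Canonical covariate order; every predictor stack carries exactly these 13.
COVARIATES = (
    "precipitation",
    "temperature",
    "vpd",
    "solar_radiation",
    "soil_moisture",
    "snow_depth",
    "population_density",
    "nighttime_light",
    "elevation",
    "dist_settlement",
    "dist_water",
    "lai",
    "npp",
)

#: Covariates redrawn each year; the rest are constant across the series.
DYNAMIC_COVARIATES = (
    "precipitation",
    "temperature",
    "vpd",
    "solar_radiation",
    "soil_moisture",
    "snow_depth",
    "lai",
    "npp",
)

ZONE_NODATA = -1


class SizingError(ValueError):
    """Grid too small to host the requested districts/settlements."""


@dataclass
class Landscape:
    """All rasters and tables of one synthetic study region.

    ``zone_raster`` holds integer district ids (1..n_districts) on every
    valid pixel and ``ZONE_NODATA`` outside the study area. ``predictors``
    maps year -> covariate name -> float raster; ``truth`` maps year ->
    species -> density raster in head/km^2.
    """

    geometry: GridGeometry
    zone_raster: np.ndarray
    settlements: pd.DataFrame
    predictors: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    truth: dict[int, dict[str, np.ndarray]] = field(default_factory=dict)
    rng_seed: int = 0

    @property
    def district_ids(self) -> np.ndarray:
        ids = np.unique(self.zone_raster)
        return ids[ids != ZONE_NODATA]

    @property
    def valid(self) -> np.ndarray:
        return self.zone_raster != ZONE_NODATA

    def district_mask(self, district_id: int) -> np.ndarray:
        return self.zone_raster == district_id


def euclidean_distance_map(geometry: GridGeometry, points_or_mask) -> np.ndarray:
    """Distance (km) from each pixel center to the nearest source pixel center.

    Parameters
    ----------
    points_or_mask
        Either a boolean raster of ``geometry.shape`` marking source pixels,
        or an (n, 2) array of planar (x, y) source points, which are first
        snapped to the pixels containing them.
    """
    arr = np.asarray(points_or_mask)
    if arr.dtype == bool and arr.shape == geometry.shape:
        mask = arr
    else:
        pts = np.atleast_2d(np.asarray(points_or_mask, dtype=float))
        if pts.size == 0:
            raise ValueError("empty source set")
        if pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of x, y")
        row, col = geometry.point_to_rowcol(pts[:, 0], pts[:, 1])
        inside = geometry.contains(row, col)
        if not inside.any():
            raise ValueError("no source point falls inside the grid")
        mask = np.zeros(geometry.shape, dtype=bool)
        mask[row[inside], col[inside]] = True
    if not mask.any():
        raise ValueError("empty source set")
    return ndimage.distance_transform_edt(
        ~mask, sampling=geometry.cell_size
    ).astype(float)


def _voronoi_zones(geometry: GridGeometry, seeds_rc: np.ndarray) -> np.ndarray:
    """Label every pixel with the id (1-based) of its nearest seed pixel."""
    xx, yy = geometry.pixel_centers()
    sx, sy = geometry.rowcol_to_point(seeds_rc[:, 0], seeds_rc[:, 1])
    # (n_seeds, n_rows, n_cols) distance stack is fine at synthetic scales
    d2 = (xx[None] - sx[:, None, None]) ** 2 + (yy[None] - sy[:, None, None]) ** 2
    return np.argmin(d2, axis=0).astype(np.int32) + 1


def generate_landscape(
    n_districts: int,
    geometry: GridGeometry,
    n_settlements_per_district: int = 12,
    seed: int = 0,
    population_median: float = 500.0,
    population_sigma: float = 1.2,
) -> Landscape:
    """Create the zone raster and settlement table of a synthetic region.

    Districts are the Voronoi cells of uniformly random seed pixels —
    contiguous, variably sized zones. Settlements scatter around each
    district's centroid (Gaussian, sd = 1/4 of the district's equivalent
    radius, resampled until inside the district) with log-normal
    populations (default median 500, sigma 1.2), spanning the hamlet-to-city
    range. Deterministic for a fixed ``seed``.
    """
    if n_districts < 2:
        raise ValueError("need at least 2 districts")
    if n_settlements_per_district < 1:
        raise ValueError("need at least 1 settlement per district")
    n_pixels = geometry.n_rows * geometry.n_cols
    if n_districts * n_settlements_per_district > n_pixels:
        raise SizingError(
            f"{n_districts} districts x {n_settlements_per_district} settlements "
            f"cannot fit on a {geometry.n_rows}x{geometry.n_cols} grid"
        )
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_pixels, size=n_districts, replace=False)
    seeds_rc = np.column_stack(np.unravel_index(flat, geometry.shape))
    zones = _voronoi_zones(geometry, seeds_rc)

    counts = np.bincount(zones.ravel(), minlength=n_districts + 1)[1:]
    if (counts < n_settlements_per_district).any():
        small = np.flatnonzero(counts < n_settlements_per_district) + 1
        raise SizingError(
            f"districts {small.tolist()} have fewer pixels than the "
            f"{n_settlements_per_district} settlements requested; "
            "use a larger grid or fewer districts"
        )

    xx, yy = geometry.pixel_centers()
    records = []
    sid = 0
    for d in range(1, n_districts + 1):
        mask = zones == d
        cx, cy = xx[mask].mean(), yy[mask].mean()
        radius = np.sqrt(mask.sum() * geometry.pixel_area / np.pi)
        sd = radius / 4.0
        placed = 0
        while placed < n_settlements_per_district:
            x = rng.normal(cx, sd)
            y = rng.normal(cy, sd)
            row, col = geometry.point_to_rowcol(x, y)
            if geometry.contains(row, col) and zones[row, col] == d:
                pop = float(
                    np.round(
                        np.exp(rng.normal(np.log(population_median), population_sigma))
                    )
                )
                records.append(
                    {
                        "settlement_id": sid,
                        "x": float(x),
                        "y": float(y),
                        "population": pop,
                        "district_id": d,
                    }
                )
                sid += 1
                placed += 1
    settlements = pd.DataFrame.from_records(records)
    return Landscape(
        geometry=geometry,
        zone_raster=zones,
        settlements=settlements,
        rng_seed=seed,
    )


def _smooth_field(
    shape: tuple[int, int], sigma_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance Gaussian random field: white noise convolved at sigma_px."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_px)
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _kernel_sum(
    geometry: GridGeometry, settlements: pd.DataFrame, weights: np.ndarray, bw_km: float
) -> np.ndarray:
    """Sum of per-settlement Gaussian kernels scaled by ``weights``."""
    out = np.zeros(geometry.shape, dtype=float)
    row, col = geometry.point_to_rowcol(
        settlements["x"].to_numpy(), settlements["y"].to_numpy()
    )
    np.add.at(out, (row, col), weights)
    return ndimage.gaussian_filter(out, sigma=bw_km / geometry.cell_size)


def generate_predictors(
    landscape: Landscape,
    years: list[int],
    length_scale: float = 10.0,
    seed: int = 0,
    anomaly_fraction: float = 0.3,
) -> Landscape:
    """Fill ``landscape.predictors`` with the 13 covariate layers per year.

    Climate-like layers (precipitation, temperature, vpd, solar_radiation,
    soil_moisture, snow_depth, lai, npp) are smoothed-Gaussian-noise fields:
    a static spatial climatology plus a smaller interannual anomaly redrawn
    each year with year-specific sub-seeds (``anomaly_fraction`` of the
    total variance), mirroring how real annual climate layers are dominated
    by stable geography. Elevation is a static smoothed field plus a linear
    west-east gradient. Population density and
    nighttime light are static sums of per-settlement Gaussian kernels
    scaled by population; dist_settlement and dist_water are static
    Euclidean-distance maps. ``length_scale`` (km) sets the autocorrelation
    range of the noise fields.
    """
    if length_scale <= 0:
        raise ValueError("length_scale must be positive")
    geom = landscape.geometry
    sigma_px = length_scale / geom.cell_size
    static_rng = np.random.default_rng([seed, 0x57A71C])

    elevation = 500.0 + 300.0 * _smooth_field(geom.shape, sigma_px, static_rng)
    gradient = np.linspace(0.0, 400.0, geom.n_cols)[None, :]
    elevation = elevation + gradient

    pops = landscape.settlements["population"].to_numpy(dtype=float)
    pop_density = _kernel_sum(geom, landscape.settlements, pops, bw_km=3.0)
    pop_density /= geom.pixel_area
    night_light = np.log1p(
        _kernel_sum(geom, landscape.settlements, pops, bw_km=5.0)
    )

    pts = landscape.settlements[["x", "y"]].to_numpy()
    dist_settlement = euclidean_distance_map(geom, pts)

    # water bodies: top 2% of a static smooth field, at least one pixel
    water_field = _smooth_field(geom.shape, sigma_px, static_rng)
    water_mask = water_field >= np.quantile(water_field, 0.98)
    dist_water = euclidean_distance_map(geom, water_mask)

    static_layers = {
        "population_density": pop_density,
        "nighttime_light": night_light,
        "elevation": elevation,
        "dist_settlement": dist_settlement,
        "dist_water": dist_water,
    }

    if not 0.0 <= anomaly_fraction <= 1.0:
        raise ValueError("anomaly_fraction must be in [0, 1]")
    climatology = {}
    for li, name in enumerate(DYNAMIC_COVARIATES):
        rng = np.random.default_rng([seed, 0xC1, li])
        climatology[name] = _smooth_field(geom.shape, sigma_px, rng)
    w_clim = np.sqrt(1.0 - anomaly_fraction ** 2)

    landscape.predictors = {}
    for yi, year in enumerate(years):
        layers: dict[str, np.ndarray] = {}
        for li, name in enumerate(DYNAMIC_COVARIATES):
            rng = np.random.default_rng([seed, 1 + yi, li])
            anomaly = _smooth_field(geom.shape, sigma_px, rng)
            layers[name] = w_clim * climatology[name] + anomaly_fraction * anomaly
        layers.update({k: v.copy() for k, v in static_layers.items()})
        landscape.predictors[year] = {name: layers[name] for name in COVARIATES}
    return landscape


def _standardize(arr: np.ndarray) -> np.ndarray:
    sd = arr.std()
    return (arr - arr.mean()) / sd if sd > 0 else np.zeros_like(arr)


def generate_truth(
    landscape: Landscape,
    years: list[int],
    beta: dict[str, float] | None = None,
    trend_slope: float | np.ndarray = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    species: str = "small_ruminant",
    mean_density: float = 20.0,
    decay_length: float = 10.0,
) -> Landscape:
    """Fill ``landscape.truth[year][species]`` with latent density surfaces.

    The base surface is a log-linear response to the standardized base-year
    predictors times an exponential decay with distance from settlements,

        D0 = c * exp(sum_k beta_k z_k) * exp(-dist_settlement / decay_length),

    rescaled so the study-area mean equals ``mean_density`` (head/km^2).
    The z-scores saturate at +/-3 sd: settlement-kernel covariates are
    extremely heavy-tailed, and without saturation a handful of city pixels
    would carry densities thousands of times the regional mean — far beyond
    the dynamic range real density maps exhibit.
    Year ``t`` (offset from the first year) is ``D0 * (1 + trend_slope * t)``
    plus Gaussian noise of sd ``noise_sd``, clipped at zero. ``trend_slope``
    is the fractional density change per year (scalar or per-pixel raster).
    Deterministic for a fixed ``seed``.
    """
    if decay_length <= 0:
        raise ValueError("decay_length must be positive")
    if not landscape.predictors:
        raise ValueError("generate_predictors must run before generate_truth")
    if beta is None:
        beta = {"population_density": 0.8, "temperature": 0.5, "precipitation": 0.3}
    unknown = set(beta) - set(COVARIATES)
    if unknown:
        raise ValueError(f"beta names not among the covariates: {sorted(unknown)}")

    geom = landscape.geometry
    base_year = years[0]
    base_pred = landscape.predictors[base_year]
    log_d = np.zeros(geom.shape, dtype=float)
    for name, b in beta.items():
        log_d += b * np.clip(_standardize(base_pred[name]), -3.0, 3.0)
    d0 = np.exp(log_d) * np.exp(-base_pred["dist_settlement"] / decay_length)
    d0 *= mean_density / d0.mean()

    rng = np.random.default_rng([seed, 0xD0])
    slope = np.asarray(trend_slope, dtype=float)
    n_clipped = 0
    n_total = 0
    for year in years:
        t = year - base_year
        surface = d0 * (1.0 + slope * t)
        if noise_sd > 0:
            surface = surface + rng.normal(0.0, noise_sd, size=geom.shape)
        clipped = surface < 0
        n_clipped += int(clipped.sum())
        n_total += surface.size
        landscape.truth.setdefault(year, {})[species] = np.clip(surface, 0.0, None)
    if n_clipped:
        logger.info(
            "generate_truth(%s): clipped %.3f%% of pixel-years at zero",
            species,
            100.0 * n_clipped / n_total,
        )
    return landscape


def aggregate_truth_to_census(
    landscape: Landscape, round_headcounts: bool = False
) -> pd.DataFrame:
    """Aggregate the latent truth to an exact district census table.

    Returns one record per (district_id, year, species) with ``headcount``
    (density summed over district pixels times pixel area) and ``area_km2``
    (pixel count times pixel area). With ``round_headcounts`` the heads are
    rounded to integers; by default they are exact reals.
    """
    if not landscape.truth:
        raise ValueError("landscape has no truth surfaces to aggregate")
    geom = landscape.geometry
    ids = landscape.district_ids
    zone = landscape.zone_raster
    records = []
    for year, by_species in sorted(landscape.truth.items()):
        for species, surface in sorted(by_species.items()):
            sums = ndimage.sum_labels(surface, labels=zone, index=ids)
            counts = ndimage.sum_labels(np.ones_like(surface), labels=zone, index=ids)
            for d, s, c in zip(ids, sums, counts):
                head = s * geom.pixel_area
                records.append(
                    {
                        "district_id": int(d),
                        "year": int(year),
                        "species": species,
                        "headcount": float(np.round(head) if round_headcounts else head),
                        "area_km2": float(c * geom.pixel_area),
                    }
                )
    return pd.DataFrame.from_records(records)


def default_landscape(
    seed: int = 42,
    n_districts: int = 24,
    shape: tuple[int, int] = (200, 200),
    n_settlements_per_district: int = 12,
    years: tuple[int, ...] = tuple(range(2000, 2020)),
    trend_slope: float = 0.02,
    noise_sd: float = 2.0,
    species: tuple[str, ...] = SPECIES,
) -> Landscape:
    """Reference synthetic region: 24 districts on a 200x200 km grid of 1 km
    cells, 12 settlements per district, a 20-year series with a 2%/yr
    injected trend and additive noise, two species (horses at a tenth of the
    small-ruminant mean density, as in extensive rangeland systems)."""
    geom = GridGeometry(n_rows=shape[0], n_cols=shape[1], cell_size=1.0)
    ls = generate_landscape(
        n_districts, geom, n_settlements_per_district=n_settlements_per_district,
        seed=seed,
    )
    generate_predictors(ls, list(years), length_scale=10.0, seed=seed + 1)
    for si, sp in enumerate(species):
        mean_density = 20.0 if sp == "small_ruminant" else 2.0
        generate_truth(
            ls,
            list(years),
            trend_slope=trend_slope,
            noise_sd=noise_sd * (mean_density / 20.0),
            seed=seed + 2 + si,
            species=sp,
            mean_density=mean_density,
        )
    return ls
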