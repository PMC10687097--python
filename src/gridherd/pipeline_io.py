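"""End-to-end orchestration and all external formats.

Rasters are written as single-band float32 GeoTIFFs (via tifffile) carrying
ModelPixelScale/ModelTiepoint tags for the planar grid and a GDAL nodata
tag; a JSON manifest records the grid geometry, seeds and configuration so
a run is fully reconstructable. Density maps follow the deposit naming rule
``sr_<year>.tif`` (small ruminants) / ``hr_<year>.tif`` (horses); trend
surfaces are 4-band stacks (tau, Sen slope, p, significance).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import adjustment, census, downscaler, trends
from .grids import GridGeometry
from .sampling import SplitSpec, split_train_test
from .surfaces import DensitySurface
from .synthetic import (
    COVARIATES,
    SPECIES,
    Landscape,
    aggregate_truth_to_census,
    default_landscape,
)

logger = logging.getLogger(__name__)

SPECIES_ACRONYM = {"small_ruminant": "sr", "horse": "hr"}

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _geo_extratags(geometry: GridGeometry) -> list:
    scale = (float(geometry.cell_size), float(geometry.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(geometry.origin_x), float(geometry.origin_y), 0.0)
    nodata = str(geometry.nodata).encode() + b"\x00"
    return [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GDAL_NODATA, "s", len(nodata), nodata, True),
    ]


def write_raster(path: Path, values: np.ndarray, geometry: GridGeometry) -> Path:
    """Write a float32 (or multi-band) raster with planar geo-tags."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(
        path,
        np.asarray(values, dtype=np.float32),
        photometric="minisblack",
        extratags=_geo_extratags(geometry),
    )
    return path


def read_raster(path: Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def write_density_raster(surface: DensitySurface, out_dir: Path) -> Path:
    """Write one species-year density surface under the deposit naming rule."""
    if surface.species not in SPECIES_ACRONYM:
        raise ValueError(
            f"unknown species {surface.species!r}; "
            f"expected one of {sorted(SPECIES_ACRONYM)}"
        )
    name = f"{SPECIES_ACRONYM[surface.species]}_{surface.year}.tif"
    return write_raster(Path(out_dir) / name, surface.values, surface.geometry)


def write_trend_raster(ts: trends.TrendSurface, out_dir: Path) -> Path:
    """4-band trend stack: tau, Sen slope, p-value, significance (0/1)."""
    acronym = SPECIES_ACRONYM.get(ts.species, ts.species)
    bands = np.stack(
        [ts.tau, ts.sen_slope, ts.p_value, ts.significant.astype(float)]
    )
    path = write_raster(Path(out_dir) / f"{acronym}_trend.tif", bands, ts.geometry)
    sidecar = {
        "bands": ["tau", "sen_slope", "p_value", "significant"],
        "alpha": ts.alpha,
        "species": ts.species,
    }
    Path(out_dir, f"{acronym}_trend.json").write_text(json.dumps(sidecar, indent=2))
    return path


def save_landscape(landscape: Landscape, out_dir: Path) -> Path:
    """Persist a landscape: zone/predictor/truth rasters, settlements, manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    geom = landscape.geometry
    write_raster(out_dir / "zones.tif", landscape.zone_raster.astype(np.float32), geom)
    landscape.settlements.to_csv(out_dir / "settlements.csv", index=False)
    for year, layers in landscape.predictors.items():
        for name, arr in layers.items():
            write_raster(out_dir / "predictors" / f"{name}_{year}.tif", arr, geom)
    for year, by_species in landscape.truth.items():
        for sp, arr in by_species.items():
            write_raster(out_dir / "truth" / f"{sp}_{year}.tif", arr, geom)
    manifest = {
        "geometry": geom.to_dict(),
        "rng_seed": landscape.rng_seed,
        "years": sorted(landscape.predictors),
        "covariates": list(COVARIATES),
        "truth_species": sorted(
            {sp for d in landscape.truth.values() for sp in d}
        ),
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path


def load_landscape(in_dir: Path) -> Landscape:
    """Load a landscape written by :func:`save_landscape`, geometry-checked."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    geom = GridGeometry.from_dict(manifest["geometry"])
    zones = read_raster(in_dir / "zones.tif").astype(np.int32)
    settlements = pd.read_csv(in_dir / "settlements.csv")
    landscape = Landscape(
        geometry=geom,
        zone_raster=zones,
        settlements=settlements,
        rng_seed=int(manifest.get("rng_seed", 0)),
    )
    bad = []
    for year in manifest["years"]:
        layers = {}
        for name in manifest["covariates"]:
            arr = read_raster(in_dir / "predictors" / f"{name}_{year}.tif")
            if arr.shape != geom.shape:
                bad.append(f"{name}_{year}.tif: {arr.shape} != {geom.shape}")
                continue
            layers[name] = arr
        landscape.predictors[int(year)] = layers
        for sp in manifest.get("truth_species", []):
            p = in_dir / "truth" / f"{sp}_{year}.tif"
            if p.exists():
                arr = read_raster(p)
                if arr.shape != geom.shape:
                    bad.append(f"truth/{sp}_{year}.tif: {arr.shape} != {geom.shape}")
                    continue
                landscape.truth.setdefault(int(year), {})[sp] = arr
    if bad:
        raise ValueError("layers do not match the manifest grid: " + "; ".join(bad))
    return landscape


def load_census_csv(path: Path) -> pd.DataFrame:
    """Load and schema-check a census CSV (area_km2 optional)."""
    table = pd.read_csv(Path(path))
    census.validate_census(table, require_area="area_km2" in table.columns)
    return table


@dataclass
class RunConfig:
    """Configuration of an end-to-end run on a synthetic landscape.

    ``buffer_km``/``train_fraction`` of None means "choose them from the
    model-selection experiment on ``selection_year``". The RF tuning grid
    defaults here are deliberately small so a full 2-species x 20-year run
    stays cheap; pass the wider grids for a thorough search.
    """

    out_dir: str = "gridherd_run"
    species: tuple[str, ...] = SPECIES
    years: tuple[int, ...] = tuple(range(2000, 2020))
    selection_year: int = 2015
    k: int = 10
    buffer_km: float | None = None
    train_fraction: float | None = None
    seed: int = 42
    alpha: float = 0.05
    run_experiment: bool = True
    tune_per_year: bool = False
    mtry_grid: tuple[int, ...] = (4, 13)
    ntree_grid: tuple[int, ...] = (200,)
    cv_folds: int = 5
    cv_repeats: int = 2
    ntree_fixed: int = 150
    mtry_fixed: int = 4
    n_districts: int = 24
    grid_shape: tuple[int, int] = (200, 200)
    n_settlements_per_district: int = 12
    trend_slope: float = 0.02
    noise_sd: float = 2.0
    trends_on: str = "adjusted"

    def __post_init__(self) -> None:
        years = tuple(sorted(self.years))
        if years != tuple(range(years[0], years[-1] + 1)):
            raise ValueError("years must be sorted and contiguous")
        unknown = set(self.species) - set(SPECIES_ACRONYM)
        if unknown:
            raise ValueError(f"unknown species {sorted(unknown)}")
        if self.selection_year not in years:
            raise ValueError("selection_year must be one of years")


@dataclass
class RunResult:
    out_dir: Path
    landscape: Landscape
    census_table: pd.DataFrame
    experiment_grid: pd.DataFrame | None
    buffer_km: float
    train_fraction: float
    adjusted: dict[str, dict[int, DensitySurface]] = field(default_factory=dict)
    predicted: dict[str, dict[int, DensitySurface]] = field(default_factory=dict)
    trend: dict[str, trends.TrendSurface] = field(default_factory=dict)


def run_pipeline(config: RunConfig, landscape: Landscape | None = None) -> RunResult:
    """Execute the full workflow and write the output tree.

    Stages: synthesize (or accept) a landscape; aggregate the truth into a
    census; run the buffer x split experiment on the selection year and pick
    the design; per species-year fit a forest on the top-k settlement
    samples, predict the grid, and dasymetrically adjust to the census; per
    species compute the Mann-Kendall/Sen trend stack over the adjusted
    surfaces. Deterministic for a fixed config.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    years = list(config.years)

    if landscape is None:
        landscape = default_landscape(
            seed=config.seed,
            n_districts=config.n_districts,
            shape=config.grid_shape,
            n_settlements_per_district=config.n_settlements_per_district,
            years=tuple(years),
            trend_slope=config.trend_slope,
            noise_sd=config.noise_sd,
            species=config.species,
        )
    census_table = census.compute_density(aggregate_truth_to_census(landscape))
    census_table.to_csv(out_dir / "census.csv", index=False)

    experiment_grid = None
    buffer_km = config.buffer_km
    train_fraction = config.train_fraction
    if config.run_experiment and (buffer_km is None or train_fraction is None):
        experiment_grid = downscaler.run_experiment_grid(
            landscape,
            census_table,
            config.selection_year,
            config.species[0],
            k=config.k,
            mtry_grid=config.mtry_grid,
            ntree_grid=config.ntree_grid,
            cv_folds=config.cv_folds,
            cv_repeats=config.cv_repeats,
            seed=config.seed,
        )
        experiment_grid.to_csv(out_dir / "experiment_grid.csv", index=False)
        best_buffer, best_frac = downscaler.select_best_model(experiment_grid)
        buffer_km = best_buffer if buffer_km is None else buffer_km
        train_fraction = best_frac if train_fraction is None else train_fraction
    buffer_km = 10.0 if buffer_km is None else buffer_km
    train_fraction = 0.9 if train_fraction is None else train_fraction

    result = RunResult(
        out_dir=out_dir,
        landscape=landscape,
        census_table=census_table,
        experiment_grid=experiment_grid,
        buffer_km=buffer_km,
        train_fraction=train_fraction,
    )

    fit_rows = []
    for sp in config.species:
        sp_dir = out_dir / sp
        result.predicted[sp] = {}
        result.adjusted[sp] = {}
        for year in years:
            samples = downscaler.build_samples(
                landscape, census_table, year, sp, buffer_km=buffer_km, k=config.k
            )
            train, test = split_train_test(
                samples,
                SplitSpec(train_fraction=train_fraction, seed=config.seed + year),
            )
            if config.tune_per_year:
                rf_config, cv = downscaler.tune_hyperparameters(
                    train,
                    mtry_grid=config.mtry_grid,
                    ntree_grid=config.ntree_grid,
                    cv_folds=config.cv_folds,
                    cv_repeats=config.cv_repeats,
                    seed=config.seed,
                )
            else:
                rf_config = downscaler.RFConfig(
                    mtry=config.mtry_fixed,
                    ntree=config.ntree_fixed,
                    cv_folds=config.cv_folds,
                    cv_repeats=config.cv_repeats,
                    seed=config.seed,
                )
                cv = {"cv_r2": np.nan, "cv_rmse": np.nan, "cv_mae": np.nan}
            model, predicted = downscaler.fit_and_predict(
                train, rf_config, landscape, year, sp
            )
            test_pred = model.forest.predict(test[list(COVARIATES)].to_numpy())
            t_r2, t_rmse, t_mae = downscaler.fit_statistics(
                test["response"].to_numpy(), test_pred
            )
            totals = adjustment.census_totals(census_table, year, sp)
            adjusted, report = adjustment.adjust(
                predicted, totals, landscape.zone_raster
            )
            conservation = adjustment.verify_conservation(
                adjusted, totals, landscape.zone_raster
            )
            if not conservation["ok"].all():
                raise RuntimeError(
                    f"conservation failed for {sp} {year}: "
                    f"{conservation.loc[~conservation['ok'], 'district_id'].tolist()}"
                )
            write_density_raster(predicted, sp_dir / "predicted")
            write_density_raster(adjusted, sp_dir / "adjusted")
            report.to_csv(sp_dir / f"adjustment_{year}.csv", index=False)
            fit_rows.append(
                {
                    "species": sp, "year": year,
                    "mtry": rf_config.mtry, "ntree": rf_config.ntree,
                    **cv,
                    "test_r2": t_r2, "test_rmse": t_rmse, "test_mae": t_mae,
                    "n_train": len(train), "n_test": len(test),
                }
            )
            result.predicted[sp][year] = predicted
            result.adjusted[sp][year] = adjusted
        stack_source = result.adjusted if config.trends_on == "adjusted" else result.predicted
        stack = [stack_source[sp][y] for y in years]
        ts = trends.trend_surface(stack, alpha=config.alpha)
        result.trend[sp] = ts
        write_trend_raster(ts, out_dir / sp)

    pd.DataFrame(fit_rows).to_csv(out_dir / "fit_reports.csv", index=False)
    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "geometry": landscape.geometry.to_dict(),
        "selected": {"buffer_km": buffer_km, "train_fraction": train_fraction},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return result
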