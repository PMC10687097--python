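"""District livestock census tables: density, gap repair, merges, rasterization.

A census table is a tidy DataFrame with one record per (district_id, year,
species) carrying ``headcount`` and ``area_km2``. Densities are head/km^2.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import GridGeometry
from .synthetic import ZONE_NODATA

CENSUS_COLUMNS = ["district_id", "year", "species", "headcount", "area_km2"]


def validate_census(census: pd.DataFrame, require_area: bool = True) -> None:
    needed = CENSUS_COLUMNS if require_area else CENSUS_COLUMNS[:-1]
    missing = [c for c in needed if c not in census.columns]
    if missing:
        raise ValueError(f"census table missing columns: {missing}")
    if census.duplicated(["district_id", "year", "species"]).any():
        raise ValueError("duplicate (district_id, year, species) records")
    if (census["headcount"] < 0).any():
        raise ValueError("negative headcounts in census table")


def areas_from_zone_raster(zone_raster: np.ndarray, geometry: GridGeometry) -> pd.Series:
    """District areas (km^2) as pixel count x cell area, indexed by district id.

    Using raster-derived areas keeps census densities and raster zonal sums on
    one area definition, so conservation checks are exact.
    """
    ids, counts = np.unique(zone_raster[zone_raster != ZONE_NODATA], return_counts=True)
    return pd.Series(counts * geometry.pixel_area, index=ids, name="area_km2")


def compute_density(census: pd.DataFrame) -> pd.DataFrame:
    """Per-record density = headcount / area_km2 (head/km^2)."""
    validate_census(census)
    bad = census.loc[census["area_km2"] <= 0, "district_id"].unique()
    if bad.size:
        raise ValueError(f"non-positive area for districts {bad.tolist()}")
    out = census.copy()
    out["density"] = out["headcount"] / out["area_km2"]
    return out


def interpolate_missing_years(
    census: pd.DataFrame, required_years: list[int]
) -> pd.DataFrame:
    """Fill interior year gaps per (district, species) by linear interpolation.

    Each missing (district, year, species) headcount is interpolated in year
    between the nearest observed flanking years; the filled records get
    ``interpolated=True``. Gaps at a series boundary (no observed year on one
    side) raise — extrapolation is never performed. Values are real-valued
    (not rounded).
    """
    validate_census(census, require_area=False)
    required_years = sorted(required_years)
    frames = []
    for (district, species), grp in census.groupby(["district_id", "species"]):
        grp = grp.sort_values("year")
        observed = grp["year"].to_numpy()
        missing = [y for y in required_years if y not in set(observed)]
        boundary = [y for y in missing if y < observed.min() or y > observed.max()]
        if boundary:
            raise ValueError(
                f"district {district} ({species}): years {boundary} fall outside "
                f"the observed range {observed.min()}-{observed.max()}; "
                "no extrapolation"
            )
        base = grp.assign(interpolated=False)
        if missing:
            filled_heads = np.interp(missing, observed, grp["headcount"].to_numpy())
            fill = pd.DataFrame(
                {
                    "district_id": district,
                    "year": missing,
                    "species": species,
                    "headcount": filled_heads,
                    "interpolated": True,
                }
            )
            if "area_km2" in grp.columns:
                fill["area_km2"] = grp["area_km2"].iloc[0]
            base = pd.concat([base, fill], ignore_index=True)
        frames.append(base)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["district_id", "species", "year"]).reset_index(drop=True)


def merge_districts(census: pd.DataFrame, merge_map: dict[int, int]) -> pd.DataFrame:
    """Sum headcounts and areas of administratively merged districts.

    ``merge_map`` sends old district ids to new ids (identity for unaffected
    districts). Headcounts and areas are summed within the new id per
    (year, species). Districts merged together must cover identical year
    sets; a mismatch raises and names the gaps.
    """
    validate_census(census)
    out = census.copy()
    mapped = out["district_id"].map(lambda d: merge_map.get(d, d))
    out = out.assign(new_id=mapped)
    for (new_id, species), grp in out.groupby(["new_id", "species"]):
        per_district = grp.groupby("district_id")["year"].agg(set)
        if len(per_district) > 1:
            all_years = set.union(*per_district)
            gaps = {d: sorted(all_years - ys) for d, ys in per_district.items() if ys != all_years}
            if gaps:
                raise ValueError(
                    f"cannot merge into district {new_id} ({species}): "
                    f"missing years per source district {gaps}"
                )
    out["district_id"] = out["new_id"]
    merged = (
        out.groupby(["district_id", "year", "species"], as_index=False)[
            ["headcount", "area_km2"]
        ].sum()
    )
    merged["density"] = merged["headcount"] / merged["area_km2"]
    return merged


def rasterize_density(
    densities: pd.DataFrame,
    zone_raster: np.ndarray,
    geometry: GridGeometry,
    year: int,
    species: str,
) -> np.ndarray:
    """Paint each district's density onto its zone pixels.

    Returns a float raster with the district density on every valid pixel and
    ``geometry.nodata`` outside the zones. Every district id present in the
    zone raster must have a density for the requested (year, species).
    """
    sub = densities[(densities["year"] == year) & (densities["species"] == species)]
    lookup = dict(zip(sub["district_id"], sub["density"]))
    zone_ids = np.unique(zone_raster[zone_raster != ZONE_NODATA])
    missing = [int(z) for z in zone_ids if z not in lookup]
    if missing:
        raise ValueError(
            f"no density for districts {missing} in {species} {year}"
        )
    out = np.full(geometry.shape, geometry.nodata, dtype=float)
    max_id = int(zone_ids.max())
    table = np.full(max_id + 1, np.nan)
    for z in zone_ids:
        table[int(z)] = lookup[int(z)]
    valid = zone_raster != ZONE_NODATA
    out[valid] = table[zone_raster[valid]]
    return out
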