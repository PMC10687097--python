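"""Settlement-proxy pseudo-sampling.

Because sub-district livestock counts are unavailable, training points are
manufactured from settlements: the k most populous settlements of each
district all receive the district's census density as their response, and
covariates are read at the point's pixel or averaged over a circular buffer
around it (buffers stand in for the daily movement range of village herds
and deliberately ignore district borders).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import COVARIATES, Landscape

logger = logging.getLogger(__name__)

#: Buffer radii (km) used in the model-selection experiment; 0 = point value.
BUFFER_RADII_KM = (0, 2, 5, 10)

#: Train:test split ratios explored in the experiment grid.
SPLIT_FRACTIONS = (0.7, 0.8, 0.9)


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification.

    ``grouping='point'`` assigns rows independently (the design used to build
    the published maps); ``grouping='district'`` keeps each district's rows on
    one side, avoiding response leakage from the shared district density.
    """

    train_fraction: float = 0.9
    seed: int = 0
    grouping: str = "point"

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.grouping not in ("point", "district"):
            raise ValueError("grouping must be 'point' or 'district'")


def select_top_settlements(settlements: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """The k largest-population settlements per district.

    Districts with fewer than k settlements contribute all of them; ties in
    population break by ascending settlement_id, so selection is
    deterministic. Districts with zero settlements are logged and skipped.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    if settlements.empty:
        logger.warning("settlement table is empty; zero samples selected")
        return settlements.copy()
    ordered = settlements.sort_values(
        ["district_id", "population", "settlement_id"],
        ascending=[True, False, True],
    )
    return (
        ordered.groupby("district_id", group_keys=False)
        .head(k)
        .reset_index(drop=True)
    )


def _disc_offsets(radius_km: float, cell_size: float) -> np.ndarray:
    """(row, col) offsets of pixels whose centers lie within radius of a center."""
    r_px = int(np.floor(radius_km / cell_size))
    dr, dc = np.meshgrid(np.arange(-r_px, r_px + 1), np.arange(-r_px, r_px + 1))
    keep = (dr ** 2 + dc ** 2) * cell_size ** 2 <= radius_km ** 2
    return np.column_stack([dr[keep], dc[keep]])


def extract_features(
    landscape: Landscape,
    selected: pd.DataFrame,
    year: int,
    buffer_km: float = 0,
) -> pd.DataFrame:
    """Covariate values at each selected settlement for one year.

    ``buffer_km == 0`` reads the pixel containing the point; ``buffer_km > 0``
    averages over valid pixels whose centers fall within the circular buffer
    (buffers may cross district borders — they model physical movement, not
    administration). Returns one row per settlement with the 13 covariate
    columns plus settlement_id / district_id / year.
    """
    if year not in landscape.predictors:
        raise ValueError(f"no predictors generated for year {year}")
    geom = landscape.geometry
    layers = landscape.predictors[year]
    missing = [c for c in COVARIATES if c not in layers]
    if missing:
        raise ValueError(f"missing covariate layers: {missing}")

    rows, cols = geom.point_to_rowcol(
        selected["x"].to_numpy(), selected["y"].to_numpy()
    )
    if not geom.contains(rows, cols).all():
        bad = selected.loc[~geom.contains(rows, cols), "settlement_id"].tolist()
        raise ValueError(f"settlements outside the grid: {bad}")

    out = selected[["settlement_id", "district_id"]].copy().reset_index(drop=True)
    out["year"] = year
    out["buffer_km"] = buffer_km

    if buffer_km == 0:
        for name in COVARIATES:
            out[name] = layers[name][rows, cols]
        return out

    offsets = _disc_offsets(buffer_km, geom.cell_size)
    stack = np.stack([layers[name] for name in COVARIATES])  # (13, R, C)
    feats = np.empty((len(out), len(COVARIATES)), dtype=float)
    for i, (r, c) in enumerate(zip(rows, cols)):
        rr = r + offsets[:, 0]
        cc = c + offsets[:, 1]
        inside = (rr >= 0) & (rr < geom.n_rows) & (cc >= 0) & (cc < geom.n_cols)
        if not inside.any():
            sid = out.loc[i, "settlement_id"]
            raise ValueError(f"buffer around settlement {sid} contains no valid pixels")
        feats[i] = stack[:, rr[inside], cc[inside]].mean(axis=1)
    for j, name in enumerate(COVARIATES):
        out[name] = feats[:, j]
    return out


def attach_response(
    samples: pd.DataFrame, densities: pd.DataFrame, species: str | None = None
) -> pd.DataFrame:
    """Attach the district census density as the response of every sample.

    All samples of a district share the district's density for the sample's
    (year, species) — the central pseudo-sampling assumption. ``species``
    selects the density series; it may be omitted when ``samples`` already
    carries a species column.
    """
    needed = {"district_id", "year", "species", "density"}
    if not needed.issubset(densities.columns):
        raise ValueError(f"density table must carry columns {sorted(needed)}")
    if species is not None:
        samples = samples.assign(species=species)
    elif "species" not in samples.columns:
        raise ValueError("pass species= or provide a species column in samples")
    merged = samples.merge(
        densities[["district_id", "year", "species", "density"]],
        on=["district_id", "year", "species"],
        how="left",
    )
    if merged["density"].isna().any():
        bad = merged.loc[merged["density"].isna(), "district_id"].unique()
        raise ValueError(f"no district density for districts {bad.tolist()}")
    return merged.rename(columns={"density": "response"})


def split_train_test(
    samples: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, deterministic per seed.

    Point grouping draws round(fraction * n) rows uniformly; district
    grouping assigns whole districts to the training side until the target
    row count is reached.
    """
    n = len(samples)
    if n < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(spec.seed)
    n_train = int(round(spec.train_fraction * n))
    if spec.grouping == "point":
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        test_idx = np.sort(perm[n_train:])
    else:
        districts = samples["district_id"].unique()
        if len(districts) < 2:
            raise ValueError("district grouping needs at least 2 districts")
        order = rng.permutation(districts)
        in_train = np.zeros(n, dtype=bool)
        count = 0
        for d in order:
            if count >= n_train:
                break
            mask = (samples["district_id"] == d).to_numpy()
            in_train |= mask
            count += int(mask.sum())
        train_idx = np.flatnonzero(in_train)
        test_idx = np.flatnonzero(~in_train)
    train = samples.iloc[train_idx].reset_index(drop=True)
    test = samples.iloc[test_idx].reset_index(drop=True)
    return train, test
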