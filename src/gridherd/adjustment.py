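"""Mass-conserving dasymetric adjustment of predicted density surfaces.

Downscaled predictions rarely sum back to the census: within each district j
every pixel i is therefore rescaled by the ratio of the observed district
total O_j to the predicted district total P_j,

    Adj_i = P_i * O_j / P_j,

so the adjusted pixels reproduce the census exactly (the pycnophylactic
property) while preserving the predicted within-district pattern. O_j and
P_j are district totals in heads (density x pixel area, summed), which keeps
conservation well defined on districts of unequal pixel counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import GridGeometry
from .surfaces import DensitySurface
from .synthetic import ZONE_NODATA

logger = logging.getLogger(__name__)

#: Relative residual above which conservation is declared violated.
CONSERVATION_RTOL = 1e-9


def zonal_total(
    surface: DensitySurface, zone_raster: np.ndarray
) -> pd.Series:
    """District totals in heads: sum of density x pixel area per district."""
    if zone_raster.shape != surface.geometry.shape:
        raise ValueError(
            f"zone raster shape {zone_raster.shape} does not match "
            f"surface grid {surface.geometry.shape}"
        )
    ids = np.unique(zone_raster[zone_raster != ZONE_NODATA])
    vals = np.where(surface.valid, surface.values, 0.0)
    sums = ndimage.sum_labels(vals, labels=zone_raster, index=ids)
    return pd.Series(
        sums * surface.geometry.pixel_area, index=ids.astype(int), name="heads"
    )


def adjust(
    surface: DensitySurface,
    observed_totals: pd.Series,
    zone_raster: np.ndarray,
) -> tuple[DensitySurface, pd.DataFrame]:
    """Rescale a predicted surface to the observed district totals.

    ``observed_totals`` is indexed by district id, in heads. Degenerate
    districts are handled explicitly: O_j = 0 zeroes the district outright;
    P_j = 0 with O_j > 0 (the ratio is undefined) spreads O_j uniformly over
    the district's pixels, and the district is flagged in the report.

    Returns the adjusted surface and a per-district report with O_j, P_j,
    the applied scale and the post-adjustment residual.
    """
    if (np.asarray(observed_totals) < 0).any():
        raise ValueError("negative observed district totals")
    geom = surface.geometry
    predicted_totals = zonal_total(surface, zone_raster)
    missing = [d for d in predicted_totals.index if d not in observed_totals.index]
    if missing:
        raise ValueError(f"no observed total for districts {missing}")

    out = np.full(geom.shape, geom.nodata, dtype=float)
    valid = surface.valid & (zone_raster != ZONE_NODATA)
    out[valid] = 0.0
    rows = []
    for d, p_j in predicted_totals.items():
        o_j = float(observed_totals.loc[d])
        mask = (zone_raster == d) & valid
        n_px = int(mask.sum())
        flag = ""
        if o_j == 0.0:
            out[mask] = 0.0
            scale = 0.0
        elif p_j == 0.0:
            # Eq. undefined: fall back to uniform allocation over the district
            out[mask] = o_j / (n_px * geom.pixel_area)
            scale = np.nan
            flag = "uniform_fallback"
            logger.warning(
                "district %s: predicted total is 0 with observed %.3f heads; "
                "allocated uniformly", d, o_j,
            )
        else:
            scale = o_j / p_j
            out[mask] = surface.values[mask] * scale
        adjusted_total = float(out[mask].sum() * geom.pixel_area)
        residual = (adjusted_total - o_j) / max(o_j, 1.0)
        rows.append(
            {
                "district_id": int(d),
                "observed_heads": o_j,
                "predicted_heads": float(p_j),
                "scale": scale,
                "residual": residual,
                "flag": flag,
            }
        )
    adjusted = DensitySurface(
        values=out,
        geometry=geom,
        species=surface.species,
        year=surface.year,
        stage="adjusted",
    )
    return adjusted, pd.DataFrame(rows)


def verify_conservation(
    adjusted: DensitySurface,
    observed_totals: pd.Series,
    zone_raster: np.ndarray,
    rtol: float = CONSERVATION_RTOL,
) -> pd.DataFrame:
    """Independently recompute district residuals and flag violations.

    Residual = (sum of adjusted pixels x area - O_j) / max(O_j, 1); a
    district passes when |residual| < rtol.
    """
    totals = zonal_total(adjusted, zone_raster)
    rows = []
    for d, t in totals.items():
        o_j = float(observed_totals.loc[d])
        residual = (float(t) - o_j) / max(o_j, 1.0)
        rows.append(
            {
                "district_id": int(d),
                "observed_heads": o_j,
                "adjusted_heads": float(t),
                "residual": residual,
                "ok": bool(abs(residual) < rtol),
            }
        )
    report = pd.DataFrame(rows)
    n_bad = int((~report["ok"]).sum())
    if n_bad:
        logger.warning("conservation violated in %d districts", n_bad)
    return report


def census_totals(
    densities: pd.DataFrame, year: int, species: str
) -> pd.Series:
    """Observed district totals (heads) for one species-year from a census table."""
    sub = densities[(densities["year"] == year) & (densities["species"] == species)]
    if sub.empty:
        raise ValueError(f"census has no records for {species} {year}")
    return sub.set_index("district_id")["headcount"]
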