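"""Mann-Kendall trend test and Sen's slope, scalar and per-pixel.

The Mann-Kendall statistic S counts concordant minus discordant pairs of a
series; its variance carries the standard tie correction

    Var(S) = [n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5)] / 18,

and the normal deviate Z applies a continuity correction (S -/+ 1, 0 when
S = 0). The effect size is the tie-corrected tau-b; annual density rasters
contain tied (often zero) values, so the uncorrected tau would be biased
toward 0 there. Sen's slope is the median of all pairwise slopes — a robust
trend magnitude in head/km^2/yr. With 20 annual observations the normal
approximation to S is accurate; no exact small-n tables are used.

Everything is computed in one vectorized pass over an (n_years, n_pixels)
matrix, so full-raster trend surfaces are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import GridGeometry, check_same_geometry
from .surfaces import DensitySurface


@dataclass(frozen=True)
class MKResult:
    """Mann-Kendall test of one series."""

    S: float
    var_S: float
    Z: float
    tau: float
    p: float
    n: int


@dataclass
class TrendSurface:
    """Per-pixel trend rasters over an annual stack."""

    tau: np.ndarray
    sen_slope: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    geometry: GridGeometry
    species: str
    alpha: float


def _mk_matrix(data: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                          np.ndarray, np.ndarray]:
    """Vectorized MK over columns of an (n, m) matrix.

    Returns (S, var_S, Z, tau, p), each of length m.
    """
    n, m = data.shape
    ii, jj = np.triu_indices(n, k=1)
    diffs = data[jj] - data[ii]  # (n_pairs, m)
    s = np.sign(diffs).sum(axis=0)

    # tie-group sizes per column: sort, label runs, histogram the labels
    xs = np.sort(data, axis=0)
    new_group = np.ones((n, m), dtype=bool)
    new_group[1:] = xs[1:] != xs[:-1]
    gid = np.cumsum(new_group, axis=0) - 1  # group index within column
    counts = np.zeros((n, m), dtype=np.int64)
    cols = np.broadcast_to(np.arange(m), (n, m))
    np.add.at(counts, (gid, cols), 1)
    t = counts.astype(float)
    tie_var = (t * (t - 1) * (2 * t + 5)).sum(axis=0)
    tie_pairs = (t * (t - 1) / 2).sum(axis=0)

    var_s = (n * (n - 1) * (2 * n + 5) - tie_var) / 18.0

    z = np.zeros(m)
    sd = np.sqrt(var_s, where=var_s > 0, out=np.zeros(m))
    pos = (s > 0) & (sd > 0)
    neg = (s < 0) & (sd > 0)
    z[pos] = (s[pos] - 1) / sd[pos]
    z[neg] = (s[neg] + 1) / sd[neg]

    d = n * (n - 1) / 2.0
    denom = np.sqrt((d - tie_pairs) * d)
    tau = np.divide(s, denom, where=denom > 0, out=np.zeros(m, dtype=float))

    p = np.where(var_s > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
    return s.astype(float), var_s, z, tau, p


def mann_kendall(series) -> MKResult:
    """Mann-Kendall test of a single series (implicit unit time step)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("need a 1-d series of length >= 4")
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    s, var_s, z, tau, p = _mk_matrix(x[:, None])
    return MKResult(
        S=float(s[0]), var_S=float(var_s[0]), Z=float(z[0]),
        tau=float(tau[0]), p=float(p[0]), n=x.size,
    )


def _sen_matrix(data: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Median pairwise slope per column of an (n, m) matrix."""
    ii, jj = np.triu_indices(len(times), k=1)
    dt = times[jj] - times[ii]
    keep = dt != 0
    if not keep.any():
        raise ValueError("all time pairs are duplicates; Sen's slope undefined")
    slopes = (data[jj][keep] - data[ii][keep]) / dt[keep][:, None]
    return np.median(slopes, axis=0)


def sens_slope(series, times=None) -> float:
    """Median of all pairwise slopes (x_j - x_i)/(t_j - t_i), i < j.

    ``times`` defaults to 0..n-1; pairs with duplicate times are excluded.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d series of length >= 2")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, float)
    if t.shape != x.shape:
        raise ValueError("times must match the series length")
    return float(_sen_matrix(x[:, None], t)[0])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def trend_surface(
    stack: list[DensitySurface],
    alpha: float = 0.05,
    fdr: bool = False,
) -> TrendSurface:
    """Per-pixel Mann-Kendall tau, Sen's slope and p over an annual stack.

    The stack must share one grid and be ordered (strictly increasing years).
    Pixels invalid in any year are skipped. The significance mask fires at
    raw p < alpha (matching the usual per-pixel masking of trend maps);
    ``fdr=True`` switches to Benjamini-Hochberg adjusted p-values.
    """
    if len(stack) < 4:
        raise ValueError("need at least 4 annual surfaces")
    geom = stack[0].geometry
    species = stack[0].species
    years = np.array([s.year for s in stack], dtype=float)
    if not (np.diff(years) > 0).all():
        raise ValueError("stack years must be strictly increasing")
    for s in stack[1:]:
        check_same_geometry(geom, s.geometry)

    valid = np.logical_and.reduce([s.valid for s in stack])
    data = np.stack([s.values[valid] for s in stack])  # (n_years, n_pixels)

    tau = np.full(geom.shape, geom.nodata)
    slope = np.full(geom.shape, geom.nodata)
    pval = np.full(geom.shape, geom.nodata)
    mask = np.zeros(geom.shape, dtype=bool)

    if data.shape[1]:
        _, _, _, tau_v, p_v = _mk_matrix(data)
        slope_v = _sen_matrix(data, years)
        if fdr:
            p_v = _bh_adjust(p_v)
        tau[valid] = tau_v
        slope[valid] = slope_v
        pval[valid] = p_v
        mask[valid] = p_v < alpha

    return TrendSurface(
        tau=tau, sen_slope=slope, p_value=pval, significant=mask,
        geometry=geom, species=species, alpha=alpha,
    )
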