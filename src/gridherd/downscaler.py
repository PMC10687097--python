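"""Random-forest disaggregation of district densities to the grid.

The regression core: repeated k-fold hyperparameter tuning over (mtry,
ntree), gridded prediction from the 13 covariate layers, fit statistics
(R^2 / RMSE / MAE on cross-validation and an independent test set), the
buffer x split model-selection experiment, permutation variable importance,
and median-conditioned response curves. Forests come from scikit-learn;
everything around them (the experiment design and selection rule) is owned
here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .sampling import (
    BUFFER_RADII_KM,
    SPLIT_FRACTIONS,
    SplitSpec,
    attach_response,
    extract_features,
    select_top_settlements,
    split_train_test,
)
from .surfaces import DensitySurface
from .synthetic import COVARIATES, Landscape

#: Default tuning ranges; mtry spans sqrt(p) up to all 13 covariates.
DEFAULT_MTRY_GRID = (2, 4, 7, 13)
DEFAULT_NTREE_GRID = (250, 500)


@dataclass(frozen=True)
class RFConfig:
    """Forest hyperparameters and the CV protocol used to score them."""

    mtry: int
    ntree: int
    cv_folds: int = 10
    cv_repeats: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.mtry <= len(COVARIATES):
            raise ValueError(f"mtry must be in [1, {len(COVARIATES)}]")
        if self.ntree < 1:
            raise ValueError("ntree must be at least 1")


@dataclass
class FittedModel:
    """A trained forest plus the training context needed downstream."""

    forest: RandomForestRegressor
    config: RFConfig
    train_X: pd.DataFrame
    train_y: np.ndarray

    @property
    def response_range(self) -> tuple[float, float]:
        return float(self.train_y.min()), float(self.train_y.max())


def fit_statistics(observed, predicted) -> tuple[float, float, float]:
    """(r2, rmse, mae) of predictions against observations.

    r2 = 1 - SS_res/SS_tot; rmse = sqrt(mean squared error); mae = mean
    absolute error. A constant observed vector leaves r2 undefined (NaN).
    """
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    resid = o - p
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    mae = float(np.mean(np.abs(resid)))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    r2 = float(1.0 - np.sum(resid ** 2) / ss_tot) if ss_tot > 0 else float("nan")
    return r2, rmse, mae


def _make_forest(config: RFConfig) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=config.ntree,
        max_features=config.mtry,
        random_state=config.seed,
        n_jobs=1,
    )


def _cv_scores(
    X: np.ndarray, y: np.ndarray, config: RFConfig
) -> tuple[float, float, float]:
    """Mean (r2, rmse, mae) over repeated k-fold CV for one config."""
    rkf = RepeatedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.cv_repeats,
        random_state=config.seed,
    )
    r2s, rmses, maes = [], [], []
    for train_idx, val_idx in rkf.split(X):
        forest = _make_forest(config)
        forest.fit(X[train_idx], y[train_idx])
        r2, rmse, mae = fit_statistics(y[val_idx], forest.predict(X[val_idx]))
        r2s.append(r2)
        rmses.append(rmse)
        maes.append(mae)
    return float(np.nanmean(r2s)), float(np.mean(rmses)), float(np.mean(maes))


def tune_hyperparameters(
    train: pd.DataFrame,
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID,
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    seed: int = 0,
) -> tuple[RFConfig, dict[str, float]]:
    """Pick (mtry, ntree) minimizing mean repeated-k-fold CV RMSE.

    Every grid point is scored by the same fold structure (seeded), so the
    comparison is paired. Ties break toward the smaller forest (smaller
    ntree, then smaller mtry). Returns the winning config and its CV
    r2/rmse/mae.
    """
    if not mtry_grid or not ntree_grid:
        raise ValueError("empty hyperparameter grid")
    if len(train) < cv_folds:
        raise ValueError("fewer training rows than CV folds")
    X = train[list(COVARIATES)].to_numpy()
    y = train["response"].to_numpy()
    results = []
    for mtry, ntree in itertools.product(sorted(mtry_grid), sorted(ntree_grid)):
        config = RFConfig(
            mtry=mtry, ntree=ntree, cv_folds=cv_folds, cv_repeats=cv_repeats,
            seed=seed,
        )
        r2, rmse, mae = _cv_scores(X, y, config)
        results.append((rmse, ntree, mtry, config, r2, mae))
    results.sort(key=lambda t: (t[0], t[1], t[2]))
    best_rmse, _, _, best_config, best_r2, best_mae = results[0]
    return best_config, {"cv_r2": best_r2, "cv_rmse": best_rmse, "cv_mae": best_mae}


def fit_model(train: pd.DataFrame, config: RFConfig) -> FittedModel:
    """Train a forest on a sample table carrying the 13 covariates + response."""
    y = train["response"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training responses are constant; need >= 2 distinct values")
    X = train[list(COVARIATES)]
    forest = _make_forest(config)
    forest.fit(X.to_numpy(), y)
    return FittedModel(forest=forest, config=config, train_X=X.copy(), train_y=y)


def predict_surface(
    model: FittedModel, landscape: Landscape, year: int, species: str
) -> DensitySurface:
    """Apply a trained forest to the covariate rasters of one year."""
    if year not in landscape.predictors:
        raise ValueError(f"no predictors for year {year}")
    layers = landscape.predictors[year]
    missing = [c for c in COVARIATES if c not in layers]
    if missing:
        raise ValueError(f"missing covariate layers: {missing}")
    geom = landscape.geometry
    valid = landscape.valid
    X = np.column_stack([layers[c][valid] for c in COVARIATES])
    pred = model.forest.predict(X)
    out = np.full(geom.shape, geom.nodata, dtype=float)
    out[valid] = pred
    return DensitySurface(
        values=out, geometry=geom, species=species, year=year, stage="predicted"
    )


def fit_and_predict(
    train: pd.DataFrame,
    config: RFConfig,
    landscape: Landscape,
    year: int,
    species: str,
) -> tuple[FittedModel, DensitySurface]:
    model = fit_model(train, config)
    return model, predict_surface(model, landscape, year, species)


def build_samples(
    landscape: Landscape,
    densities: pd.DataFrame,
    year: int,
    species: str,
    buffer_km: float,
    k: int = 10,
) -> pd.DataFrame:
    """Top-k settlement samples with features and district-density response."""
    selected = select_top_settlements(landscape.settlements, k=k)
    samples = extract_features(landscape, selected, year, buffer_km=buffer_km)
    return attach_response(samples, densities, species=species)


def run_experiment_grid(
    landscape: Landscape,
    densities: pd.DataFrame,
    year: int,
    species: str,
    k: int = 10,
    buffers: tuple[float, ...] = BUFFER_RADII_KM,
    splits: tuple[float, ...] = SPLIT_FRACTIONS,
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID,
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID,
    cv_folds: int = 10,
    cv_repeats: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """The buffer x split model-selection experiment for one species-year.

    Each of the |buffers| x |splits| cells is independently tuned, fitted on
    its training partition and scored on its held-out partition. Returns one
    row per cell with CV and test r2/rmse/mae, the tuned (mtry, ntree) and
    the partition sizes.
    """
    rows = []
    for buffer_km in buffers:
        samples = build_samples(
            landscape, densities, year, species, buffer_km=buffer_km, k=k
        )
        for frac in splits:
            train, test = split_train_test(
                samples, SplitSpec(train_fraction=frac, seed=seed)
            )
            config, cv = tune_hyperparameters(
                train,
                mtry_grid=mtry_grid,
                ntree_grid=ntree_grid,
                cv_folds=cv_folds,
                cv_repeats=cv_repeats,
                seed=seed,
            )
            model = fit_model(train, config)
            test_pred = model.forest.predict(test[list(COVARIATES)].to_numpy())
            t_r2, t_rmse, t_mae = fit_statistics(test["response"].to_numpy(), test_pred)
            rows.append(
                {
                    "buffer_km": buffer_km,
                    "train_fraction": frac,
                    "split": f"{int(round(frac * 100))}:{int(round((1 - frac) * 100))}",
                    "cv_r2": cv["cv_r2"],
                    "cv_rmse": cv["cv_rmse"],
                    "cv_mae": cv["cv_mae"],
                    "test_r2": t_r2,
                    "test_rmse": t_rmse,
                    "test_mae": t_mae,
                    "mtry": config.mtry,
                    "ntree": config.ntree,
                    "n_train": len(train),
                    "n_test": len(test),
                }
            )
    return pd.DataFrame(rows)


def select_best_model(grid: pd.DataFrame) -> tuple[float, float]:
    """Pick the (buffer_km, train_fraction) cell with the best joint fit.

    A model is "best" when it has low RMSE/MAE *and* high R^2 on both the
    cross-validation and the independent-test score — no single metric
    decides. Each of the six metrics ranks the cells (errors ascending, R^2
    descending, ties sharing their average rank) and the cell with the
    lowest mean rank wins; residual ties break toward the larger buffer,
    then the larger training fraction.
    """
    metrics_asc = ["cv_rmse", "cv_mae", "test_rmse", "test_mae"]
    metrics_desc = ["cv_r2", "test_r2"]
    needed = set(metrics_asc + metrics_desc + ["buffer_km", "train_fraction"])
    missing = needed - set(grid.columns)
    if missing:
        raise ValueError(f"experiment grid missing columns: {sorted(missing)}")
    ranks = pd.DataFrame(index=grid.index)
    for m in metrics_asc:
        ranks[m] = grid[m].rank(method="average", ascending=True)
    for m in metrics_desc:
        ranks[m] = grid[m].rank(method="average", ascending=False)
    mean_rank = ranks.mean(axis=1)
    order = pd.DataFrame(
        {
            "mean_rank": mean_rank,
            "neg_buffer": -grid["buffer_km"],
            "neg_frac": -grid["train_fraction"],
        }
    ).sort_values(["mean_rank", "neg_buffer", "neg_frac"])
    best = grid.loc[order.index[0]]
    return float(best["buffer_km"]), float(best["train_fraction"])


def variable_importance(
    model: FittedModel, n_permutations: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Permutation importance: mean RMSE increase when a covariate is shuffled.

    Each covariate column of the training matrix is permuted
    ``n_permutations`` times; importance is the mean increase in RMSE over
    the baseline, floored at zero. Returned descending.
    """
    rng = np.random.default_rng(seed)
    X = model.train_X.to_numpy().copy()
    y = model.train_y
    _, base_rmse, _ = fit_statistics(y, model.forest.predict(X))
    rows = []
    for j, name in enumerate(COVARIATES):
        deltas = []
        for _ in range(n_permutations):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            _, rmse, _ = fit_statistics(y, model.forest.predict(Xp))
            deltas.append(rmse - base_rmse)
        rows.append({"covariate": name, "importance": max(0.0, float(np.mean(deltas)))})
    return (
        pd.DataFrame(rows)
        .sort_values("importance", ascending=False)
        .reset_index(drop=True)
    )


def response_curve(
    model: FittedModel, covariate: str, n_points: int = 50
) -> pd.DataFrame:
    """Model response along one covariate, the rest held at training medians."""
    if covariate not in COVARIATES:
        raise ValueError(f"unknown covariate {covariate!r}")
    med = model.train_X.median()
    lo = model.train_X[covariate].min()
    hi = model.train_X[covariate].max()
    grid_vals = np.linspace(lo, hi, n_points)
    X = np.tile(med.to_numpy(), (n_points, 1))
    j = list(COVARIATES).index(covariate)
    X[:, j] = grid_vals
    pred = model.forest.predict(X)
    return pd.DataFrame({covariate: grid_vals, "predicted_density": pred})
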