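"""Random-forest core: statistics, tuning, prediction, selection, importance."""

import numpy as np
import pandas as pd
import pytest

import gridherd as gh
from gridherd.downscaler import build_samples, fit_model
from gridherd.reference import published_selection_table

FAST_CV = dict(cv_folds=3, cv_repeats=1)


def make_training_table(rng, n=120, signal=("precipitation", "temperature")):
    X = pd.DataFrame(
        rng.normal(size=(n, len(gh.COVARIATES))), columns=list(gh.COVARIATES)
    )
    y = np.zeros(n)
    for name in signal:
        y = y + 3.0 * X[name].to_numpy()
    X["response"] = y
    return X


class TestFitStatistics:
    def test_perfect_prediction(self):
        o = np.array([1.0, 2.0, 5.0])
        r2, rmse, mae = gh.fit_statistics(o, o)
        assert (r2, rmse, mae) == (1.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        r2, rmse, mae = gh.fit_statistics([0.0, 2.0], [1.0, 1.0])
        assert rmse == pytest.approx(1.0)
        assert mae == pytest.approx(1.0)
        assert r2 == pytest.approx(0.0)

    def test_matches_reference_formulas_on_random_vectors(self, rng):
        o = rng.normal(size=100)
        p = o + rng.normal(scale=0.5, size=100)
        r2, rmse, mae = gh.fit_statistics(o, p)
        # independent oracle: explicit formula evaluation
        assert rmse == pytest.approx(np.sqrt(((o - p) ** 2).sum() / 100))
        assert mae == pytest.approx(np.abs(o - p).sum() / 100)
        assert r2 == pytest.approx(
            1 - ((o - p) ** 2).sum() / ((o - o.mean()) ** 2).sum()
        )
        assert rmse >= mae >= 0

    def test_constant_observed_r2_is_nan(self):
        r2, _, _ = gh.fit_statistics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert np.isnan(r2)


class TestTuneHyperparameters:
    def test_single_config_grid_returned(self, rng):
        train = make_training_table(rng, n=60)
        config, cv = gh.tune_hyperparameters(
            train, mtry_grid=(4,), ntree_grid=(30,), seed=1, **FAST_CV
        )
        assert (config.mtry, config.ntree) == (4, 30)
        assert cv["cv_rmse"] > 0

    def test_deterministic_per_seed(self, rng):
        train = make_training_table(rng, n=60)
        a = gh.tune_hyperparameters(
            train, mtry_grid=(2, 6), ntree_grid=(20, 40), seed=3, **FAST_CV
        )
        b = gh.tune_hyperparameters(
            train, mtry_grid=(2, 6), ntree_grid=(20, 40), seed=3, **FAST_CV
        )
        assert a[0] == b[0]
        assert a[1] == b[1]

    def test_selected_config_is_cv_rmse_argmin(self, rng):
        from gridherd.downscaler import RFConfig, _cv_scores

        train = make_training_table(rng, n=60)
        X = train[list(gh.COVARIATES)].to_numpy()
        y = train["response"].to_numpy()
        grid = [(m, t) for m in (2, 6) for t in (20, 40)]
        config, cv = gh.tune_hyperparameters(
            train, mtry_grid=(2, 6), ntree_grid=(20, 40), seed=0, **FAST_CV
        )
        scores = {
            (m, t): _cv_scores(X, y, RFConfig(m, t, 3, 1, 0))[1] for m, t in grid
        }
        assert cv["cv_rmse"] == pytest.approx(min(scores.values()))
        assert scores[(config.mtry, config.ntree)] == pytest.approx(cv["cv_rmse"])

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            gh.tune_hyperparameters(make_training_table(rng), mtry_grid=())


class TestPrediction:
    def test_constant_response_gives_constant_surface(self, small_landscape, small_census):
        samples = build_samples(
            small_landscape, small_census, 2000, "small_ruminant", buffer_km=2
        )
        samples["response"] = 7.0
        samples.loc[samples.index[0], "response"] = 7.0000001  # avoid degenerate guard
        model, surface = gh.fit_and_predict(
            samples, gh.RFConfig(mtry=4, ntree=20, seed=0),
            small_landscape, 2000, "small_ruminant",
        )
        vals = surface.values[surface.valid]
        assert vals.min() == pytest.approx(7.0, abs=1e-6)
        assert vals.max() == pytest.approx(7.0000001, abs=1e-6)

    def test_predictions_within_training_response_range(
        self, small_landscape, small_census
    ):
        samples = build_samples(
            small_landscape, small_census, 2002, "small_ruminant", buffer_km=5
        )
        model, surface = gh.fit_and_predict(
            samples, gh.RFConfig(mtry=4, ntree=50, seed=0),
            small_landscape, 2002, "small_ruminant",
        )
        lo, hi = model.response_range
        vals = surface.values[surface.valid]
        assert vals.min() >= lo - 1e-9
        assert vals.max() <= hi + 1e-9

    def test_recovers_positive_rank_correlation_with_truth(
        self, small_landscape, small_census
    ):
        from scipy.stats import spearmanr

        samples = build_samples(
            small_landscape, small_census, 2002, "small_ruminant", buffer_km=10
        )
        train, _ = gh.split_train_test(samples, gh.SplitSpec(0.9, seed=0))
        _, surface = gh.fit_and_predict(
            train, gh.RFConfig(mtry=4, ntree=100, seed=0),
            small_landscape, 2002, "small_ruminant",
        )
        truth = small_landscape.truth[2002]["small_ruminant"]
        rho = spearmanr(
            surface.values[small_landscape.valid], truth[small_landscape.valid]
        ).statistic
        assert rho > 0

    def test_missing_layer_named_in_error(self, small_landscape, small_census):
        samples = build_samples(
            small_landscape, small_census, 2000, "small_ruminant", buffer_km=0
        )
        model = fit_model(samples, gh.RFConfig(mtry=4, ntree=10, seed=0))
        broken = gh.Landscape(
            geometry=small_landscape.geometry,
            zone_raster=small_landscape.zone_raster,
            settlements=small_landscape.settlements,
            predictors={
                2000: {
                    k: v
                    for k, v in small_landscape.predictors[2000].items()
                    if k != "npp"
                }
            },
        )
        with pytest.raises(ValueError, match="npp"):
            gh.predict_surface(model, broken, 2000, "small_ruminant")


@pytest.fixture(scope="module")
def grid(small_landscape, small_census):
    return gh.run_experiment_grid(
        small_landscape, small_census, 2002, "small_ruminant",
        mtry_grid=(4,), ntree_grid=(25,), cv_folds=3, cv_repeats=1, seed=0,
    )


class TestExperimentGridAndSelection:

    def test_twelve_rows(self, grid):
        assert len(grid) == 12
        assert set(grid["buffer_km"]) == {0, 2, 5, 10}
        assert set(grid["split"]) == {"70:30", "80:20", "90:10"}

    def test_partition_sizes_sum(self, grid):
        assert (grid["n_train"] + grid["n_test"] == 36).all()

    def test_dominating_row_selected(self):
        table = published_selection_table()
        table.loc[:, ["cv_rmse", "cv_mae", "test_rmse", "test_mae"]] = 50.0
        table.loc[:, ["cv_r2", "test_r2"]] = 0.5
        table.loc[3, ["cv_rmse", "cv_mae", "test_rmse", "test_mae"]] = 1.0
        table.loc[3, ["cv_r2", "test_r2"]] = 0.99
        assert gh.select_best_model(table) == (
            table.loc[3, "buffer_km"],
            table.loc[3, "train_fraction"],
        )

    def test_published_table_selects_ten_km_ninety_ten(self):
        assert gh.select_best_model(published_selection_table()) == (10.0, 0.9)

    def test_agrees_with_rank_oracle_on_random_grids(self, rng):
        for _ in range(20):
            table = published_selection_table().copy()
            for c in ["cv_rmse", "cv_mae", "test_rmse", "test_mae"]:
                table[c] = rng.uniform(1, 100, len(table))
            for c in ["cv_r2", "test_r2"]:
                table[c] = rng.uniform(0, 1, len(table))
            # oracle: explicit rank-sum over the six metrics; ties resolved
            # toward the larger buffer, then the larger training fraction
            score = np.zeros(len(table))
            for c in ["cv_rmse", "cv_mae", "test_rmse", "test_mae"]:
                score += table[c].rank().to_numpy()
            for c in ["cv_r2", "test_r2"]:
                score += table[c].rank(ascending=False).to_numpy()
            tied = table[score == score.min()]
            expect = tied.sort_values(
                ["buffer_km", "train_fraction"], ascending=False
            ).iloc[0]
            assert gh.select_best_model(table) == (
                expect["buffer_km"],
                expect["train_fraction"],
            )


class TestVariableImportanceAndResponseCurves:
    def test_pure_noise_importances_near_zero(self, rng):
        train = make_training_table(rng, n=80, signal=())
        train["response"] = rng.normal(size=80)
        model = fit_model(train, gh.RFConfig(mtry=4, ntree=50, seed=0))
        imp = gh.variable_importance(model, n_permutations=5, seed=0)
        baseline = np.std(train["response"])
        assert (imp["importance"] < 0.5 * baseline).all()

    def test_single_driver_ranks_first(self, rng):
        train = make_training_table(rng, n=120, signal=("nighttime_light",))
        model = fit_model(train, gh.RFConfig(mtry=13, ntree=100, seed=0))
        imp = gh.variable_importance(model, n_permutations=5, seed=0)
        assert imp.iloc[0]["covariate"] == "nighttime_light"

    def test_planted_pair_in_top_three(self, rng):
        hits = 0
        for trial in range(10):
            local = np.random.default_rng(500 + trial)
            train = make_training_table(
                local, n=120, signal=("precipitation", "elevation")
            )
            train["response"] += local.normal(scale=0.5, size=len(train))
            model = fit_model(train, gh.RFConfig(mtry=4, ntree=100, seed=trial))
            imp = gh.variable_importance(model, n_permutations=5, seed=trial)
            top3 = set(imp.head(3)["covariate"])
            if {"precipitation", "elevation"} <= top3:
                hits += 1
        assert hits >= 9

    def test_flat_curve_for_ignored_covariate(self, rng):
        train = make_training_table(rng, n=100, signal=("vpd",))
        model = fit_model(train, gh.RFConfig(mtry=13, ntree=50, seed=0))
        curve = gh.response_curve(model, "snow_depth", n_points=20)
        assert curve["predicted_density"].std() < 0.1 * train["response"].std()

    def test_monotone_effect_yields_monotone_curve(self, rng):
        from scipy.stats import spearmanr

        train = make_training_table(rng, n=150, signal=("soil_moisture",))
        model = fit_model(train, gh.RFConfig(mtry=13, ntree=100, seed=0))
        curve = gh.response_curve(model, "soil_moisture", n_points=30)
        rho = spearmanr(curve["soil_moisture"], curve["predicted_density"]).statistic
        assert rho > 0.9

    def test_unknown_covariate_rejected(self, rng):
        train = make_training_table(rng, n=50)
        model = fit_model(train, gh.RFConfig(mtry=4, ntree=10, seed=0))
        with pytest.raises(ValueError, match="unknown covariate"):
            gh.response_curve(model, "roads")
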