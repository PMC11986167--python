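"""Metrics, LOOCV, hyperparameter tuning and greedy feature fusion."""

import numpy as np
import pandas as pd
import pytest

import vinespec as vs
from vinespec.regression import (
    DTSpec,
    GBRSpec,
    default_grid,
    loocv_evaluate,
    r_squared,
    rmse,
    select_feature_subset,
    tune_hyperparameters,
)


class TestMetrics:
    def test_rmse_hand_values(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([3, 4], [0, 0]) == pytest.approx(np.sqrt(12.5))
        assert rmse([1.0], [3.0]) == pytest.approx(2.0)

    def test_r_squared_hand_values(self):
        y = np.array([1.0, 2, 3])
        assert r_squared(y, y) == pytest.approx(1.0)
        assert r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0)
        assert r_squared(y, [1, 2, 4.0]) == pytest.approx(0.5)

    def test_agree_with_closed_form_on_random_vectors(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            n = rng.integers(5, 50)
            a = rng.normal(size=n)
            p = rng.normal(size=n)
            assert rmse(a, p) == pytest.approx(
                float(np.sqrt(np.sum((a - p) ** 2) / n)))
            tss = np.sum((a - np.mean(a)) ** 2)
            assert r_squared(a, p) == pytest.approx(
                1 - float(np.sum((a - p) ** 2)) / tss)

    def test_errors(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError, match="variance"):
            r_squared([2.0, 2.0], [1.0, 2.0])


class TestLoocv:
    def test_noiseless_linear_signal_learnable_by_deep_tree(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 1, 60)
        y = 3 * x + 1
        cv_r2, cv_rmse, oof = loocv_evaluate(x[:, None], y,
                                             DTSpec(max_depth=9))
        assert cv_r2 >= 0.95
        assert oof.shape == (60,)
        assert cv_rmse == pytest.approx(rmse(y, oof))

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            loocv_evaluate(np.arange(3.0)[:, None], np.ones(3), DTSpec())

    def test_pure_noise_target_not_overfit(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        cv_r2, _, _ = loocv_evaluate(X, y, GBRSpec(n_estimators=25))
        assert cv_r2 <= 0.1


class TestTuning:
    def test_single_spec_grid_returns_it(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(size=30)
        spec = DTSpec(max_depth=3)
        best, _ = tune_hyperparameters(x[:, None], 2 * x, [spec])
        assert best == spec

    def test_duplicate_specs_order_independent(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(size=30)
        y = 2 * x + rng.normal(0, 0.1, 30)
        grid = [DTSpec(max_depth=3), DTSpec(max_depth=5), DTSpec(max_depth=3)]
        a, _ = tune_hyperparameters(x[:, None], y, grid)
        b, _ = tune_hyperparameters(x[:, None], y, grid[::-1])
        assert a == b

    def test_winner_minimizes_cv_rmse_over_grid(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=40)
        y = 4 * x + rng.normal(0, 0.2, 40)
        grid = [DTSpec(max_depth=d, min_samples_leaf=m)
                for d in (1, 3, 5) for m in (2, 6)]
        best, best_rmse = tune_hyperparameters(x[:, None], y, grid)
        for spec in grid:
            _, r, _ = loocv_evaluate(x[:, None], y, spec)
            assert best_rmse <= r + 1e-12

    def test_staged_gbr_tuning_matches_per_spec_loocv(self):
        # the shared-fit staged shortcut must be exact, not approximate
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(0, 0.3, 40)
        grid = [GBRSpec(ns, mf) for ns in (5, 15, 25) for mf in (None, "sqrt")]
        best, best_rmse = tune_hyperparameters(X, y, grid)
        naive = []
        for spec in grid:
            _, r, _ = loocv_evaluate(X, y, spec)
            naive.append((r, spec.complexity(), spec))
        naive_best = min(naive)
        assert best == naive_best[2]
        assert best_rmse == pytest.approx(naive_best[0], abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            tune_hyperparameters(np.arange(5.0)[:, None], np.arange(5.0), [])


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    n = 40
    signal = rng.uniform(0, 1, n)
    feats = pd.DataFrame({
        "noise1": rng.normal(size=n),
        "signal": signal,
        "noise2": rng.normal(size=n),
        "noise3": rng.normal(size=n),
    })
    y = 10 * signal + rng.normal(0, 0.3, n)
    return feats, y


class TestFeatureSelection:
    def test_recovers_relevant_feature_among_noise(self, planted):
        feats, y = planted
        grid = [DTSpec(max_depth=d) for d in (3, 5)]
        names, spec, cv = select_feature_subset(feats, y, "dt", 2, grid=grid)
        assert "signal" in names

    def test_max_size_one_is_best_single_candidate(self, planted):
        feats, y = planted
        grid = [DTSpec(max_depth=5)]
        names, _, cv = select_feature_subset(feats, y, "dt", 1, grid=grid)
        singles = {c: tune_hyperparameters(feats[[c]], y, grid)[1]
                   for c in feats.columns}
        assert names == [min(singles, key=singles.get)]
        assert cv == pytest.approx(min(singles.values()))

    def test_subset_never_worse_than_best_single(self, planted):
        feats, y = planted
        grid = [DTSpec(max_depth=d) for d in (3, 5)]
        names, _, cv = select_feature_subset(feats, y, "dt", 3, grid=grid)
        best_single = min(tune_hyperparameters(feats[[c]], y, grid)[1]
                          for c in feats.columns)
        assert cv <= best_single + 1e-12

    def test_all_candidates_passthrough(self, planted):
        feats, y = planted
        model = vs.SRIRegression(feats, y, kind="dt",
                                 grid=[DTSpec(max_depth=5)])
        res = model.fit(features="all")
        assert res.report.feature_names == list(feats.columns)


class TestModelResults:
    def test_summary_row_shape_and_star_footing(self, small_dataset):
        fm = vs.evaluate_registry(small_dataset.spectra, vs.default_registry())
        model = vs.SRIRegression(fm, small_dataset.traits["An"], kind="dt",
                                 trait="An", grid=[DTSpec(max_depth=3)])
        res = model.fit(features=["RSI_540,950", "GI"])
        row = res.summary().iloc[0]
        assert row["Variable"] == "An"
        assert row["Proposed features"] == "RSI_540,950, GI"
        assert row["Optimal parameters"] == "(3, 2, none)"
        assert res.report.cv_rmse >= 0
        assert len(res.oof_predictions) == 30

    def test_train_r2_not_below_cv_r2_in_expectation(self):
        # optimism of training fit over LOOCV, averaged over replicates
        train, cv = [], []
        groups = [vs.GroupSpec(g.name, 10, An=g.An, TSS=g.TSS, TA=g.TA)
                  for g in vs.default_groups()]
        grid = [DTSpec(max_depth=d) for d in (3, 5, 7)]
        for seed in range(20):
            ds = vs.make_dataset(groups, seed=100 + seed)
            fm = vs.evaluate_registry(ds.spectra, vs.default_registry())
            feats = fm[["RSI_540,950", "GI", "NDI_822,750,552"]]
            model = vs.SRIRegression(feats, ds.traits["An"], kind="dt",
                                     trait="An", grid=grid, seed=seed)
            res = model.fit(features="all")
            train.append(res.train_r2)
            cv.append(res.cv_r2)
        assert np.mean(train) >= np.mean(cv)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="kind"):
            vs.SRIRegression(pd.DataFrame({"a": [1.0, 2, 3]}),
                             np.arange(3.0), kind="rf")
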