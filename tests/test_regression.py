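"""Fold-safe encoding, inner-CV tuning, nested CV and importances."""

import numpy as np
import pandas as pd
import pytest

from ogttlab.regression import (
    FeatureTable,
    HyperparameterGrid,
    encode_features,
    fast_grid,
    fit_encoder,
    nested_cv_predict,
    relative_importances,
    tune_and_fit,
)


@pytest.fixture()
def mixed_table():
    rng = np.random.default_rng(0)
    n = 60
    df = pd.DataFrame({
        "subject_id": [f"S{k}" for k in range(n)],
        "x1": rng.normal(10, 2, n),
        "x2": rng.normal(0, 1, n),
        "color": rng.choice(["red", "green", "blue"], n),
    })
    return FeatureTable(df, {"x1": "numeric", "x2": "numeric", "color": "categorical"})


ONE_CONFIG = HyperparameterGrid((50,), (2,), (0.1,), (1.0,))


class TestEncoding:
    def test_training_columns_standardized(self, mixed_table):
        ids = mixed_table.subject_ids
        stats = fit_encoder(mixed_table, ids)
        X = encode_features(mixed_table, stats, ids)
        assert X["x1"].mean() == pytest.approx(0.0, abs=1e-12)
        assert X["x1"].std(ddof=0) == pytest.approx(1.0, abs=1e-12)

    def test_one_hot_rows_sum_to_one(self, mixed_table):
        ids = mixed_table.subject_ids
        stats = fit_encoder(mixed_table, ids)
        X = encode_features(mixed_table, stats, ids)
        cols = [c for c in X.columns if c.startswith("color=")]
        assert len(cols) == 3
        np.testing.assert_allclose(X[cols].sum(axis=1), 1.0)

    def test_shifted_test_fold_has_nonzero_mean(self, mixed_table):
        ids = mixed_table.subject_ids
        train, test = ids[:40], ids[40:]
        shifted = FeatureTable(mixed_table.data.copy(), dict(mixed_table.schema))
        shifted.data.loc[shifted.data["subject_id"].isin(test), "x1"] += 5.0
        stats = fit_encoder(shifted, train)
        X_te = encode_features(shifted, stats, test)
        assert abs(X_te["x1"].mean()) > 1.0

    def test_unseen_level_encodes_all_zeros(self, mixed_table):
        ids = mixed_table.subject_ids
        tweaked = FeatureTable(mixed_table.data.copy(), dict(mixed_table.schema))
        tweaked.data.loc[tweaked.data["subject_id"] == ids[-1], "color"] = "violet"
        stats = fit_encoder(tweaked, ids[:-1])
        X_te = encode_features(tweaked, stats, [ids[-1]])
        cols = [c for c in X_te.columns if c.startswith("color=")]
        assert X_te[cols].to_numpy().sum() == 0.0

    def test_missing_values_imputed_and_flagged(self, mixed_table):
        t = FeatureTable(mixed_table.data.copy(), dict(mixed_table.schema))
        t.data.loc[0, "x1"] = np.nan
        t.data.loc[1, "color"] = np.nan
        ids = t.subject_ids
        stats = fit_encoder(t, ids)
        X = encode_features(t, stats, ids)
        assert np.isfinite(X.to_numpy()).all()
        assert "color=__missing__" in X.columns
        assert X.loc["S1", "color=__missing__"] == 1.0

    def test_zero_variance_column_warned_and_zeroed(self, mixed_table):
        t = FeatureTable(mixed_table.data.copy(), dict(mixed_table.schema))
        t.data["x2"] = 3.14
        ids = t.subject_ids
        stats = fit_encoder(t, ids)
        assert any("x2" in w for w in stats.warnings)
        X = encode_features(t, stats, ids)
        assert (X["x2"] == 0.0).all()


class TestTuneAndFit:
    def test_singleton_grid_chosen_by_construction(self, mixed_table):
        ids = mixed_table.subject_ids
        stats = fit_encoder(mixed_table, ids)
        X = encode_features(mixed_table, stats, ids)
        y = np.arange(len(ids), dtype=float)
        _, chosen, _ = tune_and_fit(X, y, grid=ONE_CONFIG, seed=1)
        assert chosen == ONE_CONFIG.configurations()[0]

    def test_learnable_signal_beats_variance(self):
        rng = np.random.default_rng(2)
        n = 500
        df = pd.DataFrame({"subject_id": [f"S{k}" for k in range(n)],
                           "x1": rng.normal(0, 1, n), "x2": rng.normal(0, 1, n)})
        table = FeatureTable(df, {"x1": "numeric", "x2": "numeric"})
        y = 3.0 * df["x1"].to_numpy() + 0.1 * rng.normal(0, 1, n)
        stats = fit_encoder(table, table.subject_ids)
        X = encode_features(table, stats, table.subject_ids)
        _, _, inner_mse = tune_and_fit(X, y, grid=ONE_CONFIG, seed=0)
        assert inner_mse.min() < np.var(y)

    def test_deterministic_under_seed(self, mixed_table):
        ids = mixed_table.subject_ids
        stats = fit_encoder(mixed_table, ids)
        X = encode_features(mixed_table, stats, ids)
        rng = np.random.default_rng(3)
        y = rng.normal(0, 1, len(ids))
        _, a, mse_a = tune_and_fit(X, y, grid=fast_grid(), seed=7)
        _, b, mse_b = tune_and_fit(X, y, grid=fast_grid(), seed=7)
        assert a == b
        np.testing.assert_array_equal(mse_a, mse_b)

    def test_constant_target_flagged(self, mixed_table):
        ids = mixed_table.subject_ids
        stats = fit_encoder(mixed_table, ids)
        X = encode_features(mixed_table, stats, ids)
        with pytest.warns(RuntimeWarning, match="constant"):
            model, _, _ = tune_and_fit(X, np.full(len(ids), 2.5), grid=ONE_CONFIG, seed=0)
        assert model.predict(X.to_numpy()[:3]) == pytest.approx([2.5] * 3)


class TestImportances:
    def test_single_driver_dominates(self):
        rng = np.random.default_rng(4)
        n = 400
        df = pd.DataFrame({"subject_id": [f"S{k}" for k in range(n)],
                           "x1": rng.normal(0, 1, n), "x2": rng.normal(0, 1, n),
                           "c": rng.choice(["a", "b"], n)})
        table = FeatureTable(df, {"x1": "numeric", "x2": "numeric", "c": "categorical"})
        y = np.sin(2 * df["x1"].to_numpy()) * 3
        stats = fit_encoder(table, table.subject_ids)
        X = encode_features(table, stats, table.subject_ids)
        model, _, _ = tune_and_fit(X, y, grid=ONE_CONFIG, seed=0)
        imp = relative_importances(model, list(X.columns))
        assert imp["x1"] > 0.9
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)

    def test_indicators_aggregate_to_parent(self):
        class Fake:
            feature_importances_ = np.array([0.25, 0.25, 0.5])
        imp = relative_importances(Fake(), ["c=a", "c=b", "x1"])
        assert imp == {"c": pytest.approx(0.5), "x1": pytest.approx(0.5)}


class TestNestedCV:
    def _targets(self, table, rng, signal=False):
        ids = pd.Index(table.subject_ids)
        y = (2.0 * table.data["x1"].to_numpy() if signal
             else rng.normal(0, 1, len(ids)))
        return {"y": pd.Series(y, index=ids)}

    def test_outer_folds_partition_subjects(self, mixed_table):
        rng = np.random.default_rng(5)
        cv = nested_cv_predict(mixed_table, self._targets(mixed_table, rng),
                               outer_k=5, inner_k=5, seed=0, grid=ONE_CONFIG)
        assert sorted(cv.fold_of_subject) == sorted(mixed_table.subject_ids)
        counts = pd.Series(list(cv.fold_of_subject.values())).value_counts()
        assert counts.sum() == len(mixed_table.subject_ids)
        assert set(counts.index) == {0, 1, 2, 3, 4}

    def test_oof_predictions_cover_all_subjects(self, mixed_table):
        rng = np.random.default_rng(6)
        cv = nested_cv_predict(mixed_table, self._targets(mixed_table, rng, signal=True),
                               outer_k=5, inner_k=5, seed=0, grid=ONE_CONFIG)
        assert cv.oof_predictions["y"].notna().all()

    def test_fold_assignment_reproducible(self, mixed_table):
        rng = np.random.default_rng(7)
        t = self._targets(mixed_table, rng)
        a = nested_cv_predict(mixed_table, t, seed=3, grid=ONE_CONFIG)
        b = nested_cv_predict(mixed_table, t, seed=3, grid=ONE_CONFIG)
        assert a.fold_of_subject == b.fold_of_subject
        pd.testing.assert_frame_equal(a.oof_predictions, b.oof_predictions)

    def test_missing_targets_dropped_per_timepoint(self, mixed_table):
        rng = np.random.default_rng(8)
        t = self._targets(mixed_table, rng, signal=True)
        t["y"].iloc[::7] = np.nan
        cv = nested_cv_predict(mixed_table, t, seed=0, grid=ONE_CONFIG)
        assert cv.oof_predictions["y"].isna()[::7].all()
        assert cv.oof_predictions["y"].notna().sum() == t["y"].notna().sum()

    def test_too_few_subjects_rejected(self):
        df = pd.DataFrame({"subject_id": ["A", "B"], "x": [1.0, 2.0]})
        table = FeatureTable(df, {"x": "numeric"})
        with pytest.raises(ValueError):
            nested_cv_predict(table, {"y": pd.Series([1.0, 2.0],
                                                     index=pd.Index(["A", "B"]))},
                              outer_k=5)
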