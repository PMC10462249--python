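"""ML stage: scaling, group-wise imputation, feature scoring, triplet
ranking and predictor selection — planted-signal recovery plus
permutation-null calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom
from sklearn.linear_model import RidgeCV

from conftest import make_group_table
from rtbimr.ml import (
    aggregate_ranks,
    impute_missing,
    rank_triplets,
    scale_features,
    score_features,
    select_predictors,
)


class TestScaleFeatures:
    def test_closed_form_standardization(self):
        df = pd.DataFrame({"group": ["Sham", "Sham", "rTBI"], "v": [1.0, 2.0, 3.0]})
        out = scale_features(df)
        assert np.allclose(out["v"], [-1.2247448, 0.0, 1.2247448])

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        df = make_group_table(rng, p=5)
        once = scale_features(df)
        twice = scale_features(once)
        assert np.allclose(once.drop(columns="group"), twice.drop(columns="group"))

    def test_constant_column_zeroed_and_flagged(self):
        df = pd.DataFrame({"group": ["Sham", "Sham", "rTBI"], "v": [2.0, 2.0, 2.0]})
        out = scale_features(df)
        assert np.all(out["v"] == 0.0)
        assert out.attrs["zero_variance"] == ["v"]

    def test_missing_mask_preserved_and_invertible(self):
        rng = np.random.default_rng(1)
        df = make_group_table(rng, p=4)
        df.iloc[2, 1] = np.nan
        out = scale_features(df)
        assert out.iloc[2, 1] != out.iloc[2, 1]  # still NaN
        # unscaling with the observed-entry moments restores the data
        for col in [c for c in df.columns if c != "group"]:
            x = df[col].to_numpy()
            obs = np.isfinite(x)
            restored = out[col].to_numpy() * x[obs].std() + x[obs].mean()
            assert np.allclose(restored[obs], x[obs])


class TestImputeMissing:
    def test_identity_without_missing(self):
        rng = np.random.default_rng(2)
        df = make_group_table(rng, p=6)
        out = impute_missing(df, seed=0)
        assert np.allclose(out.drop(columns="group"), df.drop(columns="group"))

    def test_complete_after_imputation_and_observed_untouched(self):
        rng = np.random.default_rng(3)
        df = make_group_table(rng, p=6)
        df.iloc[0, 2] = np.nan
        df.iloc[11, 4] = np.nan
        out = impute_missing(df, seed=0)
        assert out.drop(columns="group").notna().all().all()
        observed = df.drop(columns="group").notna().to_numpy()
        assert np.allclose(out.drop(columns="group").to_numpy()[observed],
                           df.drop(columns="group").to_numpy()[observed])

    def test_planted_dependency_beats_mean_imputation(self):
        """C = 2A + B: random-forest imputation of hidden C entries has
        lower RMSE than group-mean filling, across 20 seeds."""
        wins = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            n = 40
            A, B = g.normal(size=n), g.normal(size=n)
            C = 2 * A + B + g.normal(0, 0.05, n)
            df = pd.DataFrame({"A": A, "B": B, "C": C})
            df.insert(0, "group", ["Sham"] * 20 + ["rTBI"] * 20)
            hide = g.choice(n, size=12, replace=False)
            truth = df["C"].copy()
            df.loc[df.index[hide], "C"] = np.nan
            imp = impute_missing(df, seed=seed)
            rf_rmse = np.sqrt(np.mean((imp["C"].iloc[hide] - truth.iloc[hide]) ** 2))
            mean_fill = df.groupby("group")["C"].transform(lambda s: s.fillna(s.mean()))
            mean_rmse = np.sqrt(np.mean((mean_fill.iloc[hide] - truth.iloc[hide]) ** 2))
            wins += rf_rmse < mean_rmse
        assert wins == 20

    def test_group_without_complete_rows_falls_back_to_means(self):
        rng = np.random.default_rng(4)
        df = make_group_table(rng, n=8, p=3)
        sham_rows = df.index[df.group == "Sham"]
        df.loc[sham_rows, "v0"] = [np.nan, 1.0, np.nan, 2.0]
        df.loc[sham_rows, "v1"] = [1.0, np.nan, 2.0, np.nan]
        out = impute_missing(df, seed=0)
        assert "Sham" in out.attrs["mean_imputed_groups"]
        assert out.drop(columns="group").notna().all().all()


class TestScoreFeatures:
    def test_planted_signal_ranked_first(self):
        """A variable with Cohen's d = 3 among 43 noise variables tops
        the pooled ranking in at least 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            t = make_group_table(rng, d=3.0)
            pool = score_features(scale_features(t), seed=seed)
            hits += pool.aggregate_rank.idxmin() == "v0"
        assert hits >= 9

    def test_every_method_scores_every_variable(self):
        rng = np.random.default_rng(5)
        t = make_group_table(rng, p=8)
        pool = score_features(t, seed=0)
        assert pool.scores.shape == (8, 6)
        assert pool.scores.notna().all().all()
        assert (pool.scores.min().min() >= 0) and (pool.scores.max().max() <= 1)
        assert sorted(pool.aggregate_rank) == list(range(1, 9))

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(6)
        t = make_group_table(rng, p=10)
        a = score_features(t, seed=42)
        b = score_features(t, seed=42)
        pd.testing.assert_frame_equal(a.scores, b.scores)
        pd.testing.assert_series_equal(a.aggregate_score, b.aggregate_score)

    def test_duplicated_variable_ties_in_symmetric_methods(self):
        rng = np.random.default_rng(7)
        t = make_group_table(rng, p=6, d=1.0)
        t["v5"] = t["v0"]  # perfect copy
        pool = score_features(t, seed=0)
        for method in ("selectkbest", "logistic"):
            assert pool.scores.loc["v0", method] == pytest.approx(
                pool.scores.loc["v5", method], rel=1e-6)

    def test_aggregate_midrank_tie_rule(self):
        scores = pd.DataFrame({"m1": [1.0, 1.0, 0.2], "m2": [0.9, 0.9, 0.1]},
                              index=["a", "b", "c"])
        agg, rank = aggregate_ranks(scores)
        assert agg["a"] == agg["b"] == 1.5
        assert agg["c"] == 3.0
        assert sorted(rank) == [1, 2, 3]

    def test_incomplete_table_rejected(self):
        rng = np.random.default_rng(8)
        t = make_group_table(rng, p=4)
        t.iloc[0, 1] = np.nan
        with pytest.raises(ValueError):
            score_features(t, seed=0)

    def test_permutation_null_selection_frequency(self):
        """With permuted labels no variable enters the top 3 more often
        than binomial chance allows (Bonferroni 95%, 100 permutations)."""
        rng = np.random.default_rng(9)
        t = make_group_table(rng, p=10)
        labels = t["group"].to_numpy().copy()
        counts = {v: 0 for v in t.columns if v != "group"}
        for perm in range(100):
            t["group"] = rng.permutation(labels)
            pool = score_features(t, seed=perm)
            for v in pool.aggregate_rank.nsmallest(3).index:
                counts[v] += 1
        bound = binom.ppf(1 - 0.05 / 10, 100, 3 / 10)
        assert max(counts.values()) <= bound


class TestRankTriplets:
    @staticmethod
    def _jointly_separable_table(rng, n=20, p=10):
        u = np.array([1.0] * (n // 2) + [-1.0] * (n // 2))
        X = rng.normal(size=(n, p))
        n1, n2 = rng.normal(0, 2.0, n), rng.normal(0, 2.0, n)
        X[:, 0] = u + n1
        X[:, 1] = u + n2
        X[:, 2] = u - n1 - n2  # sum of the three equals 3u exactly
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
        df.insert(0, "group", np.where(u > 0, "rTBI", "Sham"))
        return df

    def test_jointly_separable_triplet_wins(self):
        rng = np.random.default_rng(10)
        t = self._jointly_separable_table(rng)
        pool = score_features(t, seed=0)
        ranking = rank_triplets(pool, t, seed=0, top_k=10)
        assert set(ranking.top()) == {"v0", "v1", "v2"}
        assert ranking.table.iloc[0].loo_accuracy == 1.0

    def test_report_length_contract(self):
        rng = np.random.default_rng(11)
        t = make_group_table(rng, p=5)
        pool = score_features(t, seed=0)
        ranking = rank_triplets(pool, t, top_k=5)
        assert len(ranking.table) == 5  # min(5, C(5,3)=10)
        t3 = make_group_table(rng, p=3)
        pool3 = score_features(t3, seed=0)
        assert len(rank_triplets(pool3, t3, top_k=3).table) == 1

    def test_ordering_non_increasing(self):
        rng = np.random.default_rng(12)
        t = make_group_table(rng, p=8, d=1.5)
        pool = score_features(t, seed=0)
        ranking = rank_triplets(pool, t, top_k=6)
        acc = ranking.table.loo_accuracy.to_numpy()
        assert np.all(np.diff(acc) <= 0)
        assert all(len(set(trip)) == 3 for trip in ranking.table.variables)

    def test_pure_noise_within_permutation_band(self):
        """The top triplet's LOO accuracy on a pure-noise table falls
        inside the 95% band of its label-permutation null."""
        rng = np.random.default_rng(13)
        t = make_group_table(rng, p=10)

        def top_acc(table, seed):
            pool = score_features(table, seed=seed)
            return rank_triplets(pool, table, seed=seed, top_k=5).table.iloc[0].loo_accuracy

        observed = top_acc(t, seed=0)
        labels = t["group"].to_numpy().copy()
        null = []
        for perm in range(100):
            t["group"] = rng.permutation(labels)
            null.append(top_acc(t, seed=perm + 1))
        assert observed <= np.quantile(null, 0.95)


class TestSelectPredictors:
    @staticmethod
    def _planted_regression(seed, n=40, p=20, noise=0.1):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = 2 * X[:, 0] - 1.5 * X[:, 1] + X[:, 2] + 0.8 * X[:, 3] \
            + rng.normal(0, noise, n)
        df = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
        df["target"] = y
        df.insert(0, "group", ["Sham"] * (n // 2) + ["rTBI"] * (n // 2))
        return df

    def test_planted_linear_target_recovers_exact_set(self):
        """A target that is a 4-variable linear function (+ small noise)
        yields exactly those 4 predictors in at least 8 of 10 seeds."""
        hits = 0
        for seed in range(10):
            df = self._planted_regression(2000 + seed)
            ps = select_predictors(df, "target", seed=seed)
            hits += set(ps.predictors) == {"v0", "v1", "v2", "v3"}
        assert hits >= 8

    def test_null_target_no_generalization(self):
        """When the target is independent of every predictor, a model on
        the selected set does not beat the mean predictor on fresh data."""
        for seed in (100, 101, 102):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(20, 30))
            df = pd.DataFrame(X, columns=[f"v{i}" for i in range(30)])
            df["target"] = rng.normal(size=20)
            df.insert(0, "group", ["Sham"] * 10 + ["rTBI"] * 10)
            ps = select_predictors(df, "target", seed=seed)
            model = RidgeCV(alphas=np.logspace(-4, 2, 13))
            model.fit(df[ps.predictors].to_numpy(), df["target"].to_numpy())
            X_new = rng.normal(size=(200, 30))
            y_new = rng.normal(size=200)
            frame_new = pd.DataFrame(X_new, columns=[f"v{i}" for i in range(30)])
            pred = model.predict(frame_new[ps.predictors].to_numpy())
            r2 = 1 - np.sum((y_new - pred) ** 2) / np.sum((y_new - y_new.mean()) ** 2)
            assert r2 <= 0

    def test_target_among_predictors_rejected(self):
        df = self._planted_regression(1)
        with pytest.raises(ValueError):
            select_predictors(df, "target", seed=0,
                              predictors=["target", "v0", "v1", "v2", "v3"])

    def test_constant_target_rejected(self):
        df = self._planted_regression(2)
        df["target"] = 1.0
        with pytest.raises(ValueError):
            select_predictors(df, "target", seed=0)

    def test_deterministic_under_fixed_seed(self):
        df = self._planted_regression(3)
        a = select_predictors(df, "target", seed=5)
        b = select_predictors(df, "target", seed=5)
        assert a.predictors == b.predictors
        assert np.allclose(a.predicted, b.predicted)
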