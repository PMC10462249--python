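"""Small-cohort feature selection: classifiers and predictor search.

With 20 mice and 44 variables no single method is trusted: features are
scored by six classification/feature-selection algorithms (multilayer
perceptron, logistic regression, recursive feature elimination,
ANOVA-F SelectKBest, extra-trees importance, LASSO), pooled by mean
rank, and the top-ranked variables are combined into triplets scored by
leave-one-out (LOO) classification accuracy. For continuous targets
(risk-taking behavior, cortical Lac/Pyr) four regressors (LASSO, random
forest, ridge, linear SVR) are pooled the same way and the smallest
top-ranked predictor subset whose LOO error stays within 10% of the
all-variable model is reported.

Missing measurements are imputed group-wise: within each group, mice
with complete measurements train one random-forest regressor per
missing-valued variable, which then predicts the gaps of the incomplete
mice. Observed values are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import ExtraTreesClassifier, RandomForestRegressor
from sklearn.feature_selection import RFE, f_classif
from sklearn.linear_model import Lasso, LassoCV, LogisticRegression, Ridge, RidgeCV
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVR

CLASSIFIER_METHODS = ("mlp", "logistic", "rfe", "selectkbest", "extratrees", "lasso")
REGRESSOR_METHODS = ("lasso", "random_forest", "ridge", "svr")

#: LASSO penalty grid searched by leave-one-out CV.
LASSO_ALPHAS = np.logspace(-3, 0, 10)

#: Size of the high-importance pool from which triplets are formed.
DEFAULT_TRIPLET_POOL = 10


def _split_groups(table: pd.DataFrame):
    if "group" not in table.columns:
        raise ValueError("feature table must carry a 'group' column")
    features = table.drop(columns="group")
    y = (table["group"] == "rTBI").to_numpy(dtype=int)
    return features, y


# --------------------------------------------------------------------------
# preprocessing
# --------------------------------------------------------------------------

def scale_features(table: pd.DataFrame) -> pd.DataFrame:
    """Standardize each variable to mean 0, SD 1 over its observed entries.

    Population SD (the standard-scaler convention). The missing mask is
    preserved; zero-variance columns are set to 0 and recorded in
    ``result.attrs['zero_variance']``.
    """
    features, _ = _split_groups(table)
    out = table.copy()
    flagged = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        obs = np.isfinite(x)
        if obs.sum() < 2:
            raise ValueError(f"column {col!r} has fewer than 2 observed values")
        mu = x[obs].mean()
        sd = x[obs].std()  # population SD
        if sd == 0:
            out[col] = np.where(obs, 0.0, np.nan)
            flagged.append(col)
        else:
            out[col] = np.where(obs, (x - mu) / sd, np.nan)
    out.attrs["zero_variance"] = flagged
    return out


def impute_missing(table: pd.DataFrame, seed: int,
                   n_estimators: int = 100) -> pd.DataFrame:
    """Group-wise random-forest imputation of missing measurements.

    Within each group, complete rows are the training set: one
    random-forest regressor per missing-valued column, using all other
    columns as predictors. Incomplete rows receive the predictions
    (their own other-column gaps are filled with training means for the
    prediction input only). A group without complete rows falls back to
    group-mean imputation, recorded in ``attrs['mean_imputed_groups']``.
    """
    features, _ = _split_groups(table)
    out = table.copy()
    rng = np.random.default_rng(seed)
    fallback_groups = []
    for group, sub in table.groupby("group", sort=True):
        cols = [c for c in features.columns]
        X = sub[cols]
        complete = X.notna().all(axis=1)
        missing_cols = [c for c in cols if X[c].isna().any()]
        if not missing_cols:
            continue
        if complete.sum() < 2:
            fallback_groups.append(group)
            for c in missing_cols:
                out.loc[sub.index[X[c].isna()], c] = X[c].mean()
            continue
        train = X[complete]
        col_means = train.mean()
        for c in missing_cols:
            predictors = [p for p in cols if p != c]
            model = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.integers(2 ** 31)),
            )
            model.fit(train[predictors].to_numpy(), train[c].to_numpy())
            rows = sub.index[X[c].isna()]
            Xp = X.loc[rows, predictors].fillna(col_means[predictors])
            out.loc[rows, c] = model.predict(Xp.to_numpy())
    out.attrs["mean_imputed_groups"] = fallback_groups
    return out


# --------------------------------------------------------------------------
# classification feature scoring
# --------------------------------------------------------------------------

@dataclass
class FeatureScorePool:
    """Per-method importances plus the pooled ranking.

    ``scores`` is variables x methods with each method normalized to
    [0, 1]; ``aggregate_score`` is the mean of per-method midranks
    (lower = more important); ``aggregate_rank`` is the 1..n permutation
    ordering variables by aggregate score (ties broken by column order).
    """

    scores: pd.DataFrame
    aggregate_score: pd.Series
    aggregate_rank: pd.Series


def _normalize(v: np.ndarray) -> np.ndarray:
    v = np.abs(np.asarray(v, dtype=float))
    m = v.max()
    return v / m if m > 0 else np.zeros_like(v)


def _lasso_loo_alpha(X: np.ndarray, y: np.ndarray, seed: int) -> float:
    cv = LassoCV(alphas=LASSO_ALPHAS, cv=min(len(y), 20), max_iter=50_000,
                 random_state=seed)
    with np.errstate(all="ignore"):
        cv.fit(X, y)
    return float(cv.alpha_)


def aggregate_ranks(scores: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    """Mean-midrank pooling of per-method scores (lower rank = better)."""
    ranks = scores.apply(lambda col: rankdata(-col.to_numpy(), method="average"))
    agg = ranks.mean(axis=1)
    order = np.lexsort((np.arange(len(agg)), agg.to_numpy()))
    perm = np.empty(len(agg), dtype=int)
    perm[order] = np.arange(1, len(agg) + 1)
    return agg, pd.Series(perm, index=scores.index, name="aggregate_rank")


def score_features(table: pd.DataFrame, seed: int) -> FeatureScorePool:
    """Score every variable's importance for rTBI-vs-Sham classification.

    Requires a complete (post-imputation) table. Each method's absolute
    importances are scaled to [0, 1]; pooling is by mean midrank.
    """
    features, y = _split_groups(table)
    if features.isna().any().any():
        raise ValueError("table must be complete; run impute_missing first")
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("each class needs at least 2 subjects")
    X = features.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rs = lambda: int(rng.integers(2 ** 31))

    scores = {}

    # lbfgs: full-batch quasi-Newton, the reliable choice at n = 20 where
    # stochastic solvers leave the weights near their random init
    mlp = MLPClassifier(hidden_layer_sizes=(8,), alpha=1e-3, max_iter=2000,
                        solver="lbfgs", random_state=rs())
    with np.errstate(all="ignore"):
        mlp.fit(X, y)
    scores["mlp"] = _normalize(np.abs(mlp.coefs_[0]).sum(axis=1))

    logreg = LogisticRegression(max_iter=2000)
    logreg.fit(X, y)
    scores["logistic"] = _normalize(logreg.coef_.ravel())

    rfe = RFE(LogisticRegression(max_iter=2000), n_features_to_select=1)
    rfe.fit(X, y)
    n = X.shape[1]
    scores["rfe"] = _normalize((n - rfe.ranking_).astype(float))

    f_scores, _ = f_classif(X, y)
    scores["selectkbest"] = _normalize(np.nan_to_num(f_scores))

    trees = ExtraTreesClassifier(n_estimators=200, random_state=rs())
    trees.fit(X, y)
    scores["extratrees"] = _normalize(trees.feature_importances_)

    alpha = _lasso_loo_alpha(X, y.astype(float), rs())
    lasso = Lasso(alpha=alpha, max_iter=50_000)
    with np.errstate(all="ignore"):
        lasso.fit(X, y.astype(float))
    scores["lasso"] = _normalize(lasso.coef_)

    frame = pd.DataFrame(scores, index=features.columns)[list(CLASSIFIER_METHODS)]
    agg, rank = aggregate_ranks(frame)
    return FeatureScorePool(scores=frame, aggregate_score=agg, aggregate_rank=rank)


# --------------------------------------------------------------------------
# triplet ranking
# --------------------------------------------------------------------------

@dataclass
class TripletRanking:
    """Top variable triplets with LOO classification accuracy."""

    table: pd.DataFrame  # columns: variables, loo_accuracy, importance_sum

    def top(self) -> tuple[str, str, str]:
        return tuple(self.table.iloc[0]["variables"])


def _loo_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    correct = 0
    idx = np.arange(len(y))
    for i in idx:
        tr = idx != i
        clf = LogisticRegression(max_iter=2000)
        clf.fit(X[tr], y[tr])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return correct / len(y)


def rank_triplets(pool: FeatureScorePool, table: pd.DataFrame, seed: int = 0,
                  top_k: int = DEFAULT_TRIPLET_POOL, n_report: int = 5,
                  exhaustive: bool = False) -> TripletRanking:
    """Rank 3-variable classifiers built from the high-importance pool.

    Candidates are all triplets of the ``top_k`` variables by aggregate
    rank (or of every variable with ``exhaustive``); each is scored by
    the LOO accuracy of a logistic classifier on those 3 variables, with
    ties broken by summed aggregate importance (lower mean rank wins).
    """
    features, y = _split_groups(table)
    if features.isna().any().any():
        raise ValueError("table must be complete; run impute_missing first")
    variables = list(pool.aggregate_rank.sort_values().index)
    if len(variables) < 3:
        raise ValueError("need at least 3 scored variables")
    candidates = variables if exhaustive else variables[:top_k]

    rows = []
    for trip in combinations(candidates, 3):
        X = features[list(trip)].to_numpy(dtype=float)
        acc = _loo_accuracy(X, y)
        imp = float(pool.aggregate_score[list(trip)].sum())
        rows.append({"variables": trip, "loo_accuracy": acc,
                     "importance_sum": imp})
    frame = pd.DataFrame(rows).sort_values(
        ["loo_accuracy", "importance_sum"], ascending=[False, True],
        kind="mergesort").reset_index(drop=True)
    return TripletRanking(table=frame.head(min(n_report, len(frame))))


# --------------------------------------------------------------------------
# predictor selection for continuous targets
# --------------------------------------------------------------------------

@dataclass
class PredictorSet:
    """Minimal predictor subset for one continuous target."""

    target: str
    predictors: list[str]
    predicted: pd.Series
    observed: pd.Series
    metrics: dict = field(default_factory=dict)
    scores: pd.DataFrame | None = None
    aggregate_score: pd.Series | None = None


def _loo_regression(X: np.ndarray, y: np.ndarray, make_model) -> np.ndarray:
    pred = np.empty(len(y))
    idx = np.arange(len(y))
    for i in idx:
        tr = idx != i
        model = make_model()
        model.fit(X[tr], y[tr])
        pred[i] = model.predict(X[i:i + 1])[0]
    return pred


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum((y - pred) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")


def select_predictors(table: pd.DataFrame, target: str, seed: int,
                      predictors: list[str] | None = None,
                      max_subset: int = 10,
                      tolerance: float = 0.10) -> PredictorSet:
    """Find the smallest predictor set matching the all-variable model.

    Four regressors score every candidate predictor by absolute
    coefficient / importance; scores are pooled by mean rank. Candidate
    subsets grow down the pooled ranking and are evaluated by LOO mean
    absolute error of a ridge regression; the smallest subset within
    ``tolerance`` (relative) of the all-variable LOO error is returned.
    """
    features, _ = _split_groups(table)
    if target not in features.columns:
        raise ValueError(f"target {target!r} not in table")
    if predictors is None:
        predictors = [c for c in features.columns if c != target]
    if target in predictors:
        raise ValueError("target must not appear among the predictors")
    if len(predictors) < 5:
        raise ValueError("need at least 5 candidate predictors")
    sub = features[[target] + predictors]
    if sub.isna().any().any():
        raise ValueError("table must be complete; run impute_missing first")

    y = features[target].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant target cannot be predicted")
    X = features[predictors].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rs = lambda: int(rng.integers(2 ** 31))

    scores = {}
    alpha = _lasso_loo_alpha(X, y, rs())
    lasso = Lasso(alpha=alpha, max_iter=50_000)
    with np.errstate(all="ignore"):
        lasso.fit(X, y)
    scores["lasso"] = _normalize(lasso.coef_)

    forest = RandomForestRegressor(n_estimators=200, random_state=rs())
    forest.fit(X, y)
    scores["random_forest"] = _normalize(forest.feature_importances_)

    ridge = Ridge(alpha=1.0)
    ridge.fit(X, y)
    scores["ridge"] = _normalize(ridge.coef_)

    svr = LinearSVR(C=1.0, max_iter=50_000, random_state=rs())
    with np.errstate(all="ignore"):
        svr.fit(X, y)
    scores["svr"] = _normalize(svr.coef_)

    frame = pd.DataFrame(scores, index=predictors)[list(REGRESSOR_METHODS)]
    agg, _ = aggregate_ranks(frame)
    ordered = list(agg.sort_values(kind="mergesort").index)

    # evaluation model: ridge with an internally cross-validated penalty,
    # so the all-variable reference is not crippled by a fixed alpha
    make_ridge = lambda: RidgeCV(alphas=np.logspace(-4, 2, 13))
    pred_all = _loo_regression(X, y, make_ridge)
    mae_all = float(np.mean(np.abs(y - pred_all)))

    def loo_mae(cand):
        pred = _loo_regression(features[cand].to_numpy(dtype=float), y, make_ridge)
        return float(np.mean(np.abs(y - pred))), pred

    budget = (1.0 + tolerance) * mae_all
    chosen = ordered[:max_subset]
    pred_best = None
    for k in range(1, min(max_subset, len(ordered)) + 1):
        cand = ordered[:k]
        mae_k, pred_k = loo_mae(cand)
        if mae_k <= budget:
            chosen, pred_best = cand, pred_k
            break
    if pred_best is None:
        _, pred_best = loo_mae(chosen)

    # minimality pass: a chance-correlated variable ranked above a true
    # predictor can force the prefix to overshoot; drop members (worst
    # pooled rank first) whose removal keeps the error within tolerance
    if len(chosen) > 1:
        for var in sorted(chosen, key=lambda v: -agg[v]):
            if len(chosen) == 1:
                break
            reduced = [v for v in chosen if v != var]
            mae_r, pred_r = loo_mae(reduced)
            if mae_r <= budget:
                chosen, pred_best = reduced, pred_r

    mae = float(np.mean(np.abs(y - pred_best)))
    metrics = {
        "loo_mae": mae,
        "loo_r2": _r2(y, pred_best),
        "loo_mae_all": mae_all,
        "loo_r2_all": _r2(y, pred_all),
    }
    return PredictorSet(target=target, predictors=list(chosen),
                        predicted=pd.Series(pred_best, index=features.index),
                        observed=pd.Series(y, index=features.index),
                        metrics=metrics, scores=frame, aggregate_score=agg)
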