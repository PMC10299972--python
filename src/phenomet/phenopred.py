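"""Phenomic prediction of target traits from intermediate HTFP traits.

Predicts year-site yield, overall performance (OP), yield stability
(RMSD), grain protein content or ordinal breeder decisions from up to 11
intermediate high-throughput field phenotyping traits in three categories:
dose-response curve parameters (C), timing of key stages (T) and
quantities at defined time points (Q).

Learners are partial least squares regression (PLS, linear, robust to
collinear predictors) and random forest regression (RF, nonlinear).
Cross-validation supports the resampling schemes that matter for breeding
use: leave-one-year-site-out (unseen E), leave-one-genotype-out (unseen
G), the fully crossed scheme where the training set shares neither the
test cell's genotype nor its year-site (unseen G and E), and repeated
k-fold.  Metrics: RMSE, nRMSE = 100 * RMSE / mean(observed), and
Spearman's rank correlation on pooled out-of-fold predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

__all__ = [
    "TRAIT_CATEGORIES",
    "DECISION_ORDINAL",
    "FeatureTable",
    "CVScheme",
    "PredictionReport",
    "preprocess",
    "make_folds",
    "tune_pls_ncomp",
    "cross_validate",
    "feature_importance",
]

TRAIT_CATEGORIES = {
    "C": ["r_max", "T_min", "lrc"],
    "T": ["t_PH_start", "t_PH_stop", "t_dLA_max", "t_LA_max"],
    "Q": ["PH_max", "LA_tPH15", "LA_max", "n_tiller"],
}

#: five-level breeder decision scale mapped to an ordinal response
DECISION_ORDINAL = {
    "selected": 3,
    "sister_selected": 2,
    "repeated": 1,
    "sister_repeated": 0,
    "discarded": -1,
}

N_TILLER_OUTLIER = 8000.0
RF_NTREE_GRID = (100, 250, 500, 750, 1000)


@dataclass
class FeatureTable:
    """Feature matrix plus metadata for one prediction task.

    ``df`` holds one row per (genotype, year-site) cell or per genotype,
    with feature columns, the response column and the meta keys needed to
    build folds.
    """

    df: pd.DataFrame
    features: list
    response: str
    genotype_col: str = "genotype"
    year_site_col: str = "year_site"

    def __post_init__(self):
        if len(self.features) > 11:
            raise ValueError("at most 11 intermediate-trait features are supported")
        missing = [c for c in self.features + [self.response] if c not in self.df.columns]
        if missing:
            raise ValueError(f"feature table lacks columns: {missing}")

    def X(self, idx=None):
        d = self.df if idx is None else self.df.iloc[idx]
        return d[self.features].to_numpy(float)

    def y(self, idx=None):
        d = self.df if idx is None else self.df.iloc[idx]
        return d[self.response].to_numpy(float)

    def select_categories(self, cats: str) -> "FeatureTable":
        """Restrict features to the named categories, e.g. ``"TQ"`` or ``"TQC"``."""
        feats = [f for c in cats for f in TRAIT_CATEGORIES[c.upper()] if f in self.df.columns]
        if not feats:
            raise ValueError(f"no features of categories {cats!r} present")
        return FeatureTable(self.df, feats, self.response, self.genotype_col, self.year_site_col)


@dataclass
class CVScheme:
    kind: str  # unseen_E | unseen_G | unseen_GE | kfold_repeated
    k: int = 8
    repeats: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("unseen_E", "unseen_G", "unseen_GE", "kfold_repeated"):
            raise ValueError(f"unknown CV scheme {self.kind!r}")


@dataclass
class PredictionReport:
    task: str
    learner: str
    scheme: str
    rmse: float
    nrmse: float  # percent of the observed mean
    r_s: float
    predictions: pd.DataFrame = field(repr=False, default=None)

    def to_json_dict(self):
        return {
            "task": self.task,
            "learner": self.learner,
            "scheme": self.scheme,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "r_s": self.r_s,
        }


def preprocess(table: FeatureTable, task: str) -> FeatureTable:
    """Task-specific filtering and response transforms.

    * yield task: removes tiller-count outliers (n_tiller > 8000) and rows
      with any missing dose-response (C) feature — those arise when the
      curve fit behind the C traits fails to converge;
    * decision task: maps the five-level selection scale onto the ordinal
      response (selected 3 ... discarded -1);
    * always: drops rows with a missing response.
    """
    df = table.df.copy()
    if task == "yield":
        if "n_tiller" in df.columns:
            df = df[~(df["n_tiller"] > N_TILLER_OUTLIER)]
        c_feats = [f for f in TRAIT_CATEGORIES["C"] if f in df.columns]
        if c_feats:
            df = df.dropna(subset=c_feats)
    if task == "decision":
        unknown = set(df[table.response].dropna().unique()) - set(DECISION_ORDINAL)
        if unknown:
            raise ValueError(f"unknown decision labels: {sorted(unknown)}")
        df[table.response] = df[table.response].map(DECISION_ORDINAL)
    df = df.dropna(subset=[table.response]).reset_index(drop=True)
    return FeatureTable(df, table.features, table.response, table.genotype_col, table.year_site_col)


def make_folds(table: FeatureTable, scheme: CVScheme):
    """Train/test index pairs (positional) for the requested scheme.

    unseen_E: one fold per year-site (test = that site's rows);
    unseen_G: one fold per genotype; unseen_GE: one fold per observed
    (genotype, year-site) cell, with the whole year-site *and* the whole
    genotype excluded from training; kfold_repeated: shuffled k-fold with
    the stated repeats.
    """
    df = table.df
    n = len(df)
    folds = []
    if scheme.kind == "unseen_E":
        for ys in sorted(df[table.year_site_col].unique()):
            test = np.flatnonzero(df[table.year_site_col] == ys)
            train = np.flatnonzero(df[table.year_site_col] != ys)
            folds.append((train, test))
    elif scheme.kind == "unseen_G":
        for g in sorted(df[table.genotype_col].unique()):
            test = np.flatnonzero(df[table.genotype_col] == g)
            train = np.flatnonzero(df[table.genotype_col] != g)
            folds.append((train, test))
    elif scheme.kind == "unseen_GE":
        gs = df[table.genotype_col].to_numpy()
        ys = df[table.year_site_col].to_numpy()
        for i in range(n):
            train = np.flatnonzero((gs != gs[i]) & (ys != ys[i]))
            folds.append((train, np.array([i])))
    else:
        rng = np.random.default_rng(scheme.seed)
        for _ in range(scheme.repeats):
            kf = KFold(n_splits=scheme.k, shuffle=True, random_state=int(rng.integers(2**31 - 1)))
            folds.extend((tr, te) for tr, te in kf.split(np.arange(n)))
    for train, test in folds:
        if len(train) == 0:
            raise ValueError("a fold has an empty training set")
    return folds


def _pls_pipeline(ncomp: int) -> Pipeline:
    return Pipeline(
        [("scale", StandardScaler()), ("pls", PLSRegression(n_components=ncomp, scale=False))]
    )


def tune_pls_ncomp(table: FeatureTable, max_ncomp: int | None = None, k: int = 10, seed: int = 0) -> int:
    """Number of PLS components chosen by k-fold CV over all data.

    Chosen once per task (not per outer fold), mirroring how a single
    ncomp is fixed before the resampling benchmark.  Selection uses the
    one-standard-error parsimony rule: the smallest component count whose
    CV error lies within one SE of the minimum — plain minimum-RMSE
    systematically over-selects components on noisy collinear features.
    """
    X, y = table.X(), table.y()
    max_ncomp = max_ncomp or min(len(table.features), 10)
    kf = KFold(n_splits=min(k, len(y)), shuffle=True, random_state=seed)
    splits = list(kf.split(X))
    fold_mse = np.empty((max_ncomp, len(splits)))
    for i, nc in enumerate(range(1, max_ncomp + 1)):
        for j, (tr, te) in enumerate(splits):
            model = _pls_pipeline(nc).fit(X[tr], y[tr])
            fold_mse[i, j] = np.mean((model.predict(X[te]).ravel() - y[te]) ** 2)
    mean_mse = fold_mse.mean(axis=1)
    i_min = int(np.argmin(mean_mse))
    se_min = fold_mse[i_min].std(ddof=1) / np.sqrt(len(splits))
    for i in range(max_ncomp):
        if mean_mse[i] <= mean_mse[i_min] + se_min:
            return i + 1
    return i_min + 1


def _tune_rf(X, y, seed, ntree_grid, mtry_grid, inner_k):
    """Grid search by inner CV RMSE; leave-one-out when inner_k >= n."""
    n = len(y)
    k = min(inner_k, n)
    kf = KFold(n_splits=k, shuffle=k < n, random_state=seed if k < n else None)
    best, best_rmse = None, np.inf
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            sq = 0.0
            for tr, te in kf.split(X):
                rf = RandomForestRegressor(
                    n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
                ).fit(X[tr], y[tr])
                sq += np.sum((rf.predict(X[te]) - y[te]) ** 2)
            rmse = np.sqrt(sq / n)
            if np.isfinite(rmse) and rmse < best_rmse - 1e-12:
                best, best_rmse = (ntree, mtry), rmse
    if best is None:
        raise RuntimeError("RF grid search produced no finite score")
    return best


@dataclass
class PLSSpec:
    ncomp: int = 1

    def label(self):
        return f"PLS({self.ncomp})"


@dataclass
class RFSpec:
    ntree: int | None = None  # None -> tuned per outer fold
    mtry: int | None = None
    ntree_grid: tuple = RF_NTREE_GRID
    mtry_grid: tuple | None = None
    inner_k: int = 10

    def label(self):
        return "RF"


def cross_validate(
    table: FeatureTable, model_spec, scheme: CVScheme, task: str = "", seed: int = 0
) -> PredictionReport:
    """Out-of-fold prediction benchmark for one learner and scheme.

    RF hyperparameters are re-tuned inside every training fold when left
    unset (inner 10-fold CV, or leave-one-out for the fully crossed
    scheme); PLS uses the fixed, pre-tuned component count.  Predictions
    are pooled over folds before computing RMSE, nRMSE and Spearman r_s.
    """
    folds = make_folds(table, scheme)
    X, y = table.X(), table.y()
    preds = np.full(len(y), np.nan)
    pooled_pred, pooled_obs = [], []
    for fi, (tr, te) in enumerate(folds):
        if scheme.kind == "unseen_GE":
            gs = table.df[table.genotype_col].to_numpy()
            ys = table.df[table.year_site_col].to_numpy()
            assert not set(gs[tr]) & set(gs[te]), "unseen_GE leakage: shared genotype"
            assert not set(ys[tr]) & set(ys[te]), "unseen_GE leakage: shared year-site"
        if isinstance(model_spec, PLSSpec):
            model = _pls_pipeline(min(model_spec.ncomp, len(table.features))).fit(X[tr], y[tr])
            yhat = model.predict(X[te]).ravel()
        else:
            mtry_grid = model_spec.mtry_grid or tuple(range(1, min(11, len(table.features)) + 1))
            ntree, mtry = model_spec.ntree, model_spec.mtry
            if ntree is None or mtry is None:
                inner_k = len(tr) if scheme.kind == "unseen_GE" else model_spec.inner_k
                ntree, mtry = _tune_rf(X[tr], y[tr], seed + fi, model_spec.ntree_grid, mtry_grid, inner_k)
            rf = RandomForestRegressor(
                n_estimators=ntree, max_features=mtry, random_state=seed + fi, n_jobs=1
            ).fit(X[tr], y[tr])
            yhat = rf.predict(X[te])
        pooled_pred.append(yhat)
        pooled_obs.append(y[te])
        if scheme.kind != "kfold_repeated":
            preds[te] = yhat
    yhat_all = np.concatenate(pooled_pred)
    yobs_all = np.concatenate(pooled_obs)
    rmse = float(np.sqrt(np.mean((yhat_all - yobs_all) ** 2)))
    nrmse = float(100.0 * rmse / np.mean(yobs_all))
    r_s = float(spearmanr(yobs_all, yhat_all).statistic)
    pred_df = table.df[[table.genotype_col]].copy()
    if table.year_site_col in table.df:
        pred_df[table.year_site_col] = table.df[table.year_site_col]
    pred_df["observed"] = y
    pred_df["predicted"] = preds
    return PredictionReport(
        task=task or table.response,
        learner=model_spec.label(),
        scheme=scheme.kind,
        rmse=rmse,
        nrmse=nrmse,
        r_s=r_s,
        predictions=pred_df,
    )


def feature_importance(table: FeatureTable, model_spec, seed: int = 0, n_repeats: int = 50) -> pd.DataFrame:
    """Per-feature importance with a 95% interval.

    PLS: signed score per feature summarizing the components,
    ``sum_c w_fc * q_c`` (x-weights times y-loadings, the decomposition of
    the regression coefficient onto components), on standardized features;
    the interval comes from leave-one-out jackknife over samples.
    RF: mean increase in out-of-sample squared error over ``n_repeats``
    permutations of the feature, interval from the permutation runs.
    """
    X, y = table.X(), table.y()
    feats = table.features
    if isinstance(model_spec, PLSSpec):
        nc = min(model_spec.ncomp, len(feats))

        def scores(Xa, ya):
            model = _pls_pipeline(nc).fit(Xa, ya)
            pls = model.named_steps["pls"]
            return (pls.x_weights_ * pls.y_loadings_.ravel()[None, :]).sum(axis=1)

        s_full = scores(X, y)
        n = len(y)
        jack = np.empty((n, len(feats)))
        for i in range(n):
            keep = np.arange(n) != i
            jack[i] = scores(X[keep], y[keep])
        jmean = jack.mean(axis=0)
        jse = np.sqrt((n - 1) / n * ((jack - jmean[None, :]) ** 2).sum(axis=0))
        lo, hi = s_full - 1.96 * jse, s_full + 1.96 * jse
        vals = s_full
    else:
        ntree = model_spec.ntree or 500
        mtry = model_spec.mtry or max(1, len(feats) // 3)
        rf = RandomForestRegressor(
            n_estimators=ntree, max_features=mtry, random_state=seed, n_jobs=1
        ).fit(X, y)
        imp = permutation_importance(
            rf, X, y, n_repeats=n_repeats, random_state=seed, scoring="neg_mean_squared_error"
        )
        vals = imp.importances_mean
        lo = np.percentile(imp.importances, 2.5, axis=1)
        hi = np.percentile(imp.importances, 97.5, axis=1)
    return pd.DataFrame({"feature": feats, "score": vals, "lo95": lo, "hi95": hi})
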