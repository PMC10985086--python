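"""Nested stratified cross-validated gradient-boosted risk classifier.

The estimator is a binary XGBoost model trained inside a two-level,
five-by-five case-control stratified cross-validation.  The learning-rate /
boosting-round grid is searched on the inner folds by mean ROC-AUC; the
winning combination is refit on the full outer-training partition and
evaluated on the held-out outer fold.  Missingness and near-zero-variance
filters and median imputation are fitted inside each training partition, so
no statistic of a held-out subject ever reaches a model that predicts it.

Fixed booster parameters: max_depth 10, min_child_weight 50, subsample 0.8,
binary logistic objective, log-loss evaluation; colsample_bytree 0.8 is
added when omics features are present.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from ._util import child_seed
from .preprocess import ImputationModel, apply_impute, filter_features, fit_impute

ETA_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30)
NROUNDS_GRID = (50, 100, 200, 300, 500, 700, 1000)

FIXED_PARAMS = {
    "max_depth": 10,
    "min_child_weight": 50,
    "subsample": 0.8,
    "objective": "binary:logistic",
    "eval_metric": "logloss",
    "tree_method": "hist",
    "nthread": 1,
}


@dataclass(frozen=True)
class HyperParams:
    eta: float
    nrounds: int


@dataclass
class NestedFolds:
    """Outer fold id per subject plus inner fold ids within each outer-train set."""

    outer: np.ndarray                      # shape (n,), values 0..k_outer-1
    inner: dict[int, np.ndarray]           # outer fold -> inner id per outer-train position
    seed: int
    k_outer: int
    k_inner: int

    def outer_train(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.outer != f)

    def outer_test(self, f: int) -> np.ndarray:
        return np.flatnonzero(self.outer == f)


def make_nested_folds(labels, k_outer: int = 5, k_inner: int = 5, seed: int = 0) -> NestedFolds:
    y = np.asarray(labels, dtype=int)
    for cls in (0, 1):
        if (y == cls).sum() < k_outer * k_inner:
            raise ValueError(f"class {cls} has fewer than k_outer*k_inner members")
    outer = np.empty(y.size, dtype=int)
    skf = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=child_seed(seed, "outer"))
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        outer[test_idx] = f
    inner: dict[int, np.ndarray] = {}
    for f in range(k_outer):
        tr = np.flatnonzero(outer != f)
        inn = np.empty(tr.size, dtype=int)
        skf_i = StratifiedKFold(
            n_splits=k_inner, shuffle=True, random_state=child_seed(seed, "inner", f)
        )
        for g, (_, test_idx) in enumerate(skf_i.split(np.zeros(tr.size), y[tr])):
            inn[test_idx] = g
        inner[f] = inn
    return NestedFolds(outer, inner, seed, k_outer, k_inner)


@dataclass
class FoldModel:
    fold: int
    booster: xgb.Booster
    params: HyperParams
    imputer: ImputationModel
    features: list[str]
    inner_auc: float
    inner_scores: dict = None  # (eta, nrounds) -> mean inner-CV AUC


@dataclass
class ModelBundle:
    folds: NestedFolds
    models: list[FoldModel]
    omics: bool = False


def _booster_params(eta: float, seed: int, omics: bool) -> dict:
    params = dict(FIXED_PARAMS, eta=eta, seed=seed)
    if omics:
        params["colsample_bytree"] = 0.8
    return params


def _fit_booster(X: pd.DataFrame, y: np.ndarray, eta: float, nrounds: int,
                 seed: int, omics: bool) -> xgb.Booster:
    dtrain = xgb.DMatrix(X, label=y)
    return xgb.train(_booster_params(eta, seed, omics), dtrain, num_boost_round=nrounds)


def _prepare_partition(table: pd.DataFrame, train_idx: np.ndarray):
    """Fit filters + imputation on a training partition; return (features,
    imputer, transform) where transform maps any row subset to model input."""
    filtered, _ = filter_features(table, train_idx)  # table has a RangeIndex here
    imputer = fit_impute(filtered, train_idx)
    features = list(filtered.columns)

    def transform(idx: np.ndarray) -> pd.DataFrame:
        return apply_impute(imputer, table.iloc[idx][features])

    return features, imputer, transform


def tune_and_train(folds: NestedFolds, table: pd.DataFrame, labels,
                   eta_grid=ETA_GRID, nrounds_grid=NROUNDS_GRID,
                   omics: bool = False) -> ModelBundle:
    """Grid-search (inner CV mean AUC) and refit one model per outer fold.

    For each eta the booster is trained once to max(nrounds_grid) rounds and
    truncated predictions score every nrounds candidate; boosting is
    sequential, so a truncated model is identical to one trained with fewer
    rounds.
    """
    y = np.asarray(labels, dtype=int)
    if isinstance(table, pd.DataFrame):
        table = table.reset_index(drop=True)
    else:
        table = pd.DataFrame(table)
    nrounds_sorted = sorted(nrounds_grid)
    max_rounds = nrounds_sorted[-1]
    models: list[FoldModel] = []
    for f in range(folds.k_outer):
        tr = folds.outer_train(f)
        inner = folds.inner[f]
        scores = {(eta, nr): [] for eta in eta_grid for nr in nrounds_sorted}
        for g in range(folds.k_inner):
            it_tr, it_val = tr[inner != g], tr[inner == g]
            _, _, transform = _prepare_partition(table, it_tr)
            X_tr, X_val = transform(it_tr), transform(it_val)
            if len(np.unique(y[it_val])) < 2:
                raise ValueError(f"degenerate inner fold {g} of outer fold {f}: one class only")
            for eta in eta_grid:
                booster = _fit_booster(
                    X_tr, y[it_tr], eta, max_rounds, child_seed(folds.seed, "fit", f, g, eta), omics
                )
                dval = xgb.DMatrix(X_val)
                for nr in nrounds_sorted:
                    p = booster.predict(dval, iteration_range=(0, nr))
                    scores[(eta, nr)].append(roc_auc_score(y[it_val], p))
        mean_scores = {combo: float(np.mean(v)) for combo, v in scores.items()}
        if not all(np.isfinite(list(mean_scores.values()))):
            raise ValueError(f"non-finite inner-CV AUC in outer fold {f}")
        # ties broken toward smaller eta then fewer rounds (grid order)
        best = max(
            ((eta, nr) for eta in eta_grid for nr in nrounds_sorted),
            key=lambda c: (mean_scores[c], -c[0], -c[1]),
        )
        features, imputer, transform = _prepare_partition(table, tr)
        booster = _fit_booster(
            transform(tr), y[tr], best[0], best[1], child_seed(folds.seed, "refit", f), omics
        )
        models.append(
            FoldModel(
                f, booster, HyperParams(*best), imputer, features, mean_scores[best], mean_scores
            )
        )
    return ModelBundle(folds, models, omics)


def predict_oof(bundle: ModelBundle, table: pd.DataFrame) -> np.ndarray:
    """Out-of-fold probability per subject, from the model whose outer
    training set excluded that subject."""
    if isinstance(table, pd.DataFrame):
        table = table.reset_index(drop=True)
    folds = bundle.folds
    if len(table) != folds.outer.size:
        raise ValueError("table does not match the fold map")
    probs = np.full(len(table), np.nan)
    for fm in bundle.models:
        idx = folds.outer_test(fm.fold)
        X = apply_impute(fm.imputer, table.iloc[idx][fm.features])
        probs[idx] = fm.booster.predict(xgb.DMatrix(X))
    return probs


@dataclass
class MetricSet:
    """Per-fold classification metrics with across-fold mean and 95% t-CI."""

    per_fold: pd.DataFrame
    mean: dict[str, float]
    ci_lo: dict[str, float]
    ci_hi: dict[str, float]
    counts: dict[str, int]


METRIC_NAMES = ("sensitivity", "specificity", "ppv", "npv", "f1", "auc")


def confusion_counts(labels, probs, threshold: float = 0.5) -> dict[str, int]:
    y = np.asarray(labels, dtype=int)
    pred = (np.asarray(probs, dtype=float) >= threshold).astype(int)
    return {
        "TP": int(np.sum((pred == 1) & (y == 1))),
        "FP": int(np.sum((pred == 1) & (y == 0))),
        "TN": int(np.sum((pred == 0) & (y == 0))),
        "FN": int(np.sum((pred == 0) & (y == 1))),
    }


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else np.nan


def metrics_from_counts(c: dict[str, int]) -> dict[str, float]:
    sens = _safe_div(c["TP"], c["TP"] + c["FN"])
    spec = _safe_div(c["TN"], c["TN"] + c["FP"])
    ppv = _safe_div(c["TP"], c["TP"] + c["FP"])
    npv = _safe_div(c["TN"], c["TN"] + c["FN"])
    f1 = _safe_div(2 * sens * ppv, sens + ppv) if np.isfinite(sens) and np.isfinite(ppv) else np.nan
    return {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv, "f1": f1}


def evaluate(labels, probs, folds: NestedFolds, threshold: float = 0.5) -> MetricSet:
    """Confusion-count metrics at the given threshold and rank-statistic
    ROC-AUC, per outer fold, with the across-fold mean and a 95% t-interval."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(probs, dtype=float)
    rows = []
    for f in range(folds.k_outer):
        idx = folds.outer_test(f)
        if len(np.unique(y[idx])) < 2:
            raise ValueError(f"outer fold {f} contains a single class; AUC undefined")
        c = confusion_counts(y[idx], p[idx], threshold)
        m = metrics_from_counts(c)
        m["auc"] = roc_auc_score(y[idx], p[idx])
        rows.append({"fold": f, **c, **m})
    per_fold = pd.DataFrame(rows)
    k = folds.k_outer
    tcrit = stats.t.ppf(0.975, df=k - 1)
    mean, lo, hi = {}, {}, {}
    for name in METRIC_NAMES:
        vals = per_fold[name].to_numpy()
        mean[name] = float(np.mean(vals))
        half = tcrit * np.std(vals, ddof=1) / np.sqrt(k)
        lo[name], hi[name] = mean[name] - half, mean[name] + half
    total = {k2: int(per_fold[k2].sum()) for k2 in ("TP", "FP", "TN", "FN")}
    return MetricSet(per_fold, mean, lo, hi, total)


def run_nested_cv(table: pd.DataFrame, labels, seed: int = 0,
                  eta_grid=ETA_GRID, nrounds_grid=NROUNDS_GRID,
                  k_outer: int = 5, k_inner: int = 5, omics: bool = False):
    """Convenience wrapper: folds -> tune/train -> out-of-fold predictions
    -> metrics. Returns (bundle, oof probabilities, MetricSet)."""
    folds = make_nested_folds(labels, k_outer, k_inner, seed)
    bundle = tune_and_train(folds, table, labels, eta_grid, nrounds_grid, omics)
    probs = predict_oof(bundle, table)
    return bundle, probs, evaluate(labels, probs, folds)


def permutation_null(table: pd.DataFrame, labels, n_reps: int = 100, seed: int = 0,
                     eta_grid=(0.3,), nrounds_grid=(50,),
                     k_outer: int = 5, k_inner: int = 5) -> np.ndarray:
    """Null AUC distribution: labels are permuted before fold construction
    and the full nested pipeline is re-run per repetition."""
    if n_reps < 2:
        raise ValueError("need at least 2 permutation repetitions")
    y = np.asarray(labels, dtype=int)
    out = np.empty(n_reps)
    for rep in range(n_reps):
        rng = np.random.default_rng(child_seed(seed, "perm", rep))
        y_perm = rng.permutation(y)
        _, _, ms = run_nested_cv(
            table, y_perm, seed=child_seed(seed, "permcv", rep),
            eta_grid=eta_grid, nrounds_grid=nrounds_grid, k_outer=k_outer, k_inner=k_inner,
        )
        out[rep] = ms.mean["auc"]
    return out


def empirical_p(observed: float, null: np.ndarray) -> float:
    """One-sided rank p-value with the +1 correction."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def robustness(table: pd.DataFrame, labels, n_inits: int = 100, seed: int = 0,
               eta_grid=(0.3,), nrounds_grid=(50,),
               k_outer: int = 5, k_inner: int = 5) -> np.ndarray:
    """Mean outer-CV AUC across independent re-initialisations (fold
    construction and booster seeds both re-drawn)."""
    out = np.empty(n_inits)
    for rep in range(n_inits):
        _, _, ms = run_nested_cv(
            table, labels, seed=child_seed(seed, "robust", rep),
            eta_grid=eta_grid, nrounds_grid=nrounds_grid, k_outer=k_outer, k_inner=k_inner,
        )
        out[rep] = ms.mean["auc"]
    return out
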