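"""Per-subject additive feature attributions (TreeSHAP) on the log-odds scale.

Attributions for each subject come from the model for which that subject was
out-of-fold, so explanations are never produced by a model that saw the
subject during training.  TreeSHAP guarantees additivity: the per-subject
base value plus the attribution row sums to the logit of the predicted
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb

from ._util import logit, sigmoid
from .risk_model import ModelBundle


@dataclass
class ShapMatrix:
    """subjects x features attribution values, per-subject base value
    (both log-odds), input values used, and outer-fold provenance."""

    values: pd.DataFrame
    base: pd.Series
    fold: pd.Series
    inputs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.values)

    @property
    def predicted_logit(self) -> pd.Series:
        return self.base + self.values.sum(axis=1)

    @property
    def predicted_prob(self) -> pd.Series:
        return pd.Series(sigmoid(self.predicted_logit), index=self.values.index)


def shap_values(bundle: ModelBundle, table: pd.DataFrame, mode: str = "oof") -> ShapMatrix:
    """TreeSHAP (path-dependent) attributions.

    mode="oof" (default): each subject is attributed by the booster for
    which it was out-of-fold, using that fold's imputation; additivity then
    holds against the out-of-fold predicted probability.  Features excluded
    by a fold's filters get attribution 0 for that fold's subjects.

    mode="pooled": every subject is attributed by all fold models (each
    with its own imputation) and the attributions are averaged; additivity
    then holds against the mean fold logit.  Pooling removes the systematic
    between-fold offsets that out-of-fold attribution superimposes on
    subjects with near-identical inputs, which matters when the attribution
    space is subsequently clustered.
    """
    if mode not in ("oof", "pooled"):
        raise ValueError("mode must be 'oof' or 'pooled'")
    if isinstance(table, pd.DataFrame):
        table = table.reset_index(drop=True)
    folds = bundle.folds
    if mode == "pooled":
        return _shap_pooled(bundle, table)
    all_features = list(table.columns)
    values = pd.DataFrame(0.0, index=range(len(table)), columns=all_features)
    inputs = pd.DataFrame(np.nan, index=range(len(table)), columns=all_features)
    base = pd.Series(np.nan, index=range(len(table)))
    fold_id = pd.Series(-1, index=range(len(table)), dtype=int)
    for fm in bundle.models:
        missing = [f for f in fm.features if f not in table.columns]
        if missing:
            raise ValueError(f"fold {fm.fold} expects features absent from table: {missing}")
        idx = folds.outer_test(fm.fold)
        X = fm.imputer.apply(table.iloc[idx][fm.features])
        contribs = fm.booster.predict(xgb.DMatrix(X), pred_contribs=True)
        values.iloc[idx, [values.columns.get_loc(f) for f in fm.features]] = contribs[:, :-1]
        inputs.iloc[idx, [inputs.columns.get_loc(f) for f in fm.features]] = X.to_numpy()
        base.iloc[idx] = contribs[:, -1]
        fold_id.iloc[idx] = fm.fold
    return ShapMatrix(values, base, fold_id, inputs)


def _shap_pooled(bundle: ModelBundle, table: pd.DataFrame) -> ShapMatrix:
    all_features = list(table.columns)
    n = len(table)
    values = pd.DataFrame(0.0, index=range(n), columns=all_features)
    inputs = pd.DataFrame(0.0, index=range(n), columns=all_features)
    base = pd.Series(0.0, index=range(n))
    k = len(bundle.models)
    for fm in bundle.models:
        missing = [f for f in fm.features if f not in table.columns]
        if missing:
            raise ValueError(f"fold {fm.fold} expects features absent from table: {missing}")
        X = fm.imputer.apply(table[fm.features])
        contribs = fm.booster.predict(xgb.DMatrix(X), pred_contribs=True)
        cols = [values.columns.get_loc(f) for f in fm.features]
        values.iloc[:, cols] += contribs[:, :-1] / k
        inputs.iloc[:, cols] += X.to_numpy() / k
        base += contribs[:, -1] / k
    fold_id = pd.Series(-1, index=range(n), dtype=int)
    return ShapMatrix(values, base, fold_id, inputs)


def check_additivity(shap: ShapMatrix, probs, tol: float = 1e-3) -> float:
    """Max |base + sum(attributions) - logit(p)| over subjects; raises if
    above tol."""
    err = np.max(np.abs(shap.predicted_logit.to_numpy() - logit(np.asarray(probs))))
    if err > tol:
        raise AssertionError(f"additivity violated: max error {err:.2e} > {tol}")
    return float(err)


def global_ranking(shap: ShapMatrix, top_k: int | None = None) -> pd.DataFrame:
    """Features ordered by mean |attribution| over all subjects (descending,
    ties alphabetical). Returns columns (feature, mean_abs_shap)."""
    mean_abs = shap.values.abs().mean(axis=0)
    out = (
        mean_abs.rename("mean_abs_shap")
        .rename_axis("feature")
        .reset_index()
        .sort_values(["mean_abs_shap", "feature"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    return out.head(top_k) if top_k else out


def waterfall_profile(shap: ShapMatrix, subject, top_k: int = 15) -> dict:
    """Individual risk profile: the top_k features by |attribution| with
    their input values and signed attributions, an aggregated remainder term
    for all other features, the base value and the predicted probability.
    base + sum(bars) + remainder = logit(p)."""
    if subject not in shap.values.index:
        raise KeyError(f"unknown subject {subject!r}")
    row = shap.values.loc[subject]
    order = row.abs().sort_values(ascending=False, kind="mergesort").index
    top = list(order[:top_k])
    remainder = float(row[order[top_k:]].sum())
    base = float(shap.base.loc[subject])
    logit_p = base + float(row.sum())
    return {
        "subject": subject,
        "base": base,
        "bars": [
            {"feature": f, "value": float(shap.inputs.loc[subject, f]), "shap": float(row[f])}
            for f in top
        ],
        "remainder": remainder,
        "logit": logit_p,
        "probability": float(sigmoid(logit_p)),
    }


def counterfactual_without(shap: ShapMatrix, subject, feature) -> float:
    """Predicted probability with one feature's attribution removed from the
    additive decomposition (attribution arithmetic, not a causal claim)."""
    lp = float(shap.predicted_logit.loc[subject]) - float(shap.values.loc[subject, feature])
    return float(sigmoid(lp))
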