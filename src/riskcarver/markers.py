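"""Per-cluster one-vs-rest differential-abundance testing of omics features.

For each cluster and feature, a likelihood-ratio test between two nested
logistic regressions of cluster membership — covariates + feature versus
covariates only — gives a chi-square(1) p-value; the feature coefficient's
sign gives the direction.  No minimum-detection filtering is applied and
both directions are reported.  P-values are Bonferroni-corrected within
each cluster, and the marker panel takes the top 2 most significant up- and
down-regulated features per cluster.

The logistic fits use a damped Newton solver vectorised across features
(one Hessian solve per feature per iteration), so a full panel of thousands
of (cluster, feature) tests runs in seconds.  Fits that fail to converge
within the iteration budget — e.g. under complete separation — are flagged;
their p-value still comes from the likelihood-ratio statistic at the last
iterate, whose deviance is finite even when coefficients diverge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

_MAX_ITER = 40
_TOL = 1e-10


@dataclass
class MarkerResult:
    cluster: int
    feature: str
    coef: float
    p_value: float
    p_adjusted: float
    direction: str              # "up", "down" or "none"
    converged: bool = True


def _loglik(y: np.ndarray, eta: np.ndarray) -> np.ndarray:
    # sum over rows; supports eta of shape (n,) or (n, p)
    return np.sum(y.reshape(-1, *([1] * (eta.ndim - 1))) * eta - np.logaddexp(0.0, eta), axis=0)


def _fit_logit(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, bool]:
    """Damped Newton fit of a single logistic regression; returns
    (log-likelihood, coefficients, converged)."""
    beta = np.zeros(X.shape[1])
    ll = float(_loglik(y, X @ beta))
    for _ in range(_MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            return ll, beta, False
        for _ in range(12):
            cand = beta + step
            ll_new = float(_loglik(y, X @ cand))
            if ll_new >= ll - 1e-12:
                break
            step = step / 2.0
        beta, improved = cand, ll_new - ll
        ll = ll_new
        if improved < _TOL * (abs(ll) + 1.0):
            return ll, beta, True
    return ll, beta, False


def _fit_logit_batched(y: np.ndarray, Z: np.ndarray, X: np.ndarray):
    """Fit membership ~ Z + x_j for every column x_j of X at once.

    Returns (log-likelihood per feature, feature coefficient per feature,
    converged flag per feature)."""
    n, c = Z.shape
    p = X.shape[1]
    beta = np.zeros((p, c + 1))                        # per-feature coefficients
    design = np.empty((p, n, c + 1))
    design[:, :, :c] = Z[None, :, :]
    design[:, :, c] = X.T
    ll = _loglik(y, np.einsum("pnc,pc->np", design, beta))
    active = np.ones(p, dtype=bool)
    converged = np.zeros(p, dtype=bool)
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        D = design[active]
        b = beta[active]
        eta = np.einsum("pnc,pc->pn", D, b)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = np.einsum("pnc,pn->pc", D, (y[None, :] - mu))
        hess = np.einsum("pnc,pn,pnd->pcd", D, w, D)
        try:
            step = np.linalg.solve(hess, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(h, g, rcond=None)[0] for h, g in zip(hess, grad)])
        cand = b + step
        ll_new = _loglik(y, np.einsum("pnc,pc->np", design[active], cand))
        # per-feature step halving where the likelihood worsened
        worse = ll_new < ll[active] - 1e-12
        for _ in range(12):
            if not worse.any():
                break
            step[worse] /= 2.0
            cand[worse] = b[worse] + step[worse]
            ll_new[worse] = _loglik(
                y, np.einsum("pnc,pc->np", design[active][worse], cand[worse])
            )
            worse = ll_new < ll[active] - 1e-12
        improved = ll_new - ll[active]
        beta[active] = cand
        done = improved < _TOL * (np.abs(ll_new) + 1.0)
        idx = np.flatnonzero(active)
        ll[active] = ll_new
        converged[idx[done]] = True
        active[idx[done]] = False
    return ll, beta[:, -1], converged


def de_markers(omics: pd.DataFrame, labels, covariates: pd.DataFrame | None = None,
               subset_mask=None) -> list[MarkerResult]:
    """Likelihood-ratio logistic tests of every (cluster, feature) pair.

    omics: subjects x features, numeric; rows with any missing value are
    dropped. covariates: aligned frame (e.g. a sex column); the model always
    includes an intercept. subset_mask restricts the analysis (e.g. cases
    only).
    """
    labels = np.asarray(labels)
    if subset_mask is not None:
        subset_mask = np.asarray(subset_mask, dtype=bool)
        omics = omics.loc[subset_mask]
        labels = labels[subset_mask]
        if covariates is not None:
            covariates = covariates.loc[subset_mask]
    complete = omics.notna().all(axis=1).to_numpy()
    omics = omics.loc[complete]
    labels = labels[complete]
    cov = (
        covariates.loc[complete].to_numpy(dtype=float)
        if covariates is not None
        else np.empty((len(omics), 0))
    )
    Z = np.column_stack([np.ones(len(omics)), cov])
    feats = list(omics.columns)
    X = omics.to_numpy(dtype=float)
    sds = X.std(axis=0)
    testable = sds > 0
    n_tests = len(feats)
    results: list[MarkerResult] = []
    for c in np.unique(labels):
        y = (labels == c).astype(float)
        ll_red, _, _ = _fit_logit(y, Z)
        ll_full = np.full(n_tests, ll_red)
        coefs = np.zeros(n_tests)
        conv = np.ones(n_tests, dtype=bool)
        if testable.any():
            ll_b, coef_b, conv_b = _fit_logit_batched(y, Z, X[:, testable])
            ll_full[testable] = ll_b
            coefs[testable] = coef_b
            conv[testable] = conv_b
        for j, f in enumerate(feats):
            if not testable[j]:
                results.append(MarkerResult(int(c), f, 0.0, 1.0, 1.0, "none"))
                continue
            stat = max(0.0, 2.0 * (ll_full[j] - ll_red))
            p = float(chi2.sf(stat, df=1))
            direction = "up" if coefs[j] > 0 else ("down" if coefs[j] < 0 else "none")
            results.append(
                MarkerResult(int(c), f, float(coefs[j]), p, min(1.0, p * n_tests),
                             direction, bool(conv[j]))
            )
    return results


def results_frame(results: list[MarkerResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def top_markers(results: list[MarkerResult], k: int = 2, alpha: float = 0.05) -> dict:
    """Per-cluster top-k most significant up- and down-regulated features,
    plus the deduplicated union panel for a heatmap. Features can mark more
    than one cluster but appear once in the panel."""
    df = results_frame(results)
    per_cluster = {}
    for c, grp in df.groupby("cluster"):
        entry = {}
        for direction in ("up", "down"):
            sel = (
                grp[grp["direction"] == direction]
                .sort_values(["p_adjusted", "p_value", "feature"], kind="mergesort")
                .head(k)
            )
            entry[direction] = [
                {
                    "feature": r.feature,
                    "p_adjusted": r.p_adjusted,
                    "significant": bool(r.p_adjusted <= alpha),
                }
                for r in sel.itertuples()
            ]
        per_cluster[int(c)] = entry
    panel = []
    for c in sorted(per_cluster):
        for direction in ("up", "down"):
            for m in per_cluster[c][direction]:
                if m["feature"] not in panel:
                    panel.append(m["feature"])
    return {"per_cluster": per_cluster, "panel": panel}
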